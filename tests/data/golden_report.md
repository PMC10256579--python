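# Cohort dose report

Patients: 20

## Median (range) of absorbed doses per administered activity (mGy/MBq)

| Organ | Centre 1 | Centre 2 | Centre 3 | Centre 4 |
|---|---|---|---|---|
| whole_body | 0.04 (0.03-0.07) n=5 | 0.04 (0.03-0.06) n=5 | 0.05 (0.03-0.09) n=5 | 0.05 (0.03-0.12) n=5 |

## Whole-body group comparisons (exploratory, two-sided)

- 1.1 vs 3.7 GBq (per-MBq whole-body dose): U = 40.0, p = 0.146
- rhTSH vs THW (per-MBq whole-body dose): U = 2.0, p = 0.300
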