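# iodose

Internal dosimetry of normal organs for radioiodine (Na[¹³¹I]I) therapy of
differentiated thyroid cancer, built for the multi-centre setting where
imaging schedules, fields of view and retention-measurement windows differ
between sites.

Radioiodine is administered as a fixed activity (typically 1.1 or 3.7 GBq),
yet the absorbed doses delivered to healthy organs — salivary glands, lungs,
bones, the bone marrow — vary widely between patients. Estimating those
doses from quantitative SPECT and whole-body retention measurements requires
a chain of steps, each of which this package implements and tests:

1. **System characterisation** (`iodose.calibration`) — system-volume
   calibration factor (cps/MBq) and recovery-coefficient curves RC(V)
   correcting the partial-volume loss of small objects.
2. **Quantification** (`iodose.quantify`) — counts→activity conversion,
   fixed-fraction (35%) threshold segmentation with largest-component
   selection, and VOI activity by voxel summation.
3. **Kinetics** (`iodose.kinetics`) — time-integrated activity Ã and its
   coefficient TIAC = Ã/A₀:
   * mono-exponential organ fits, `Ã = A(0)/λ`;
   * single-time-point extrapolation `Ã = A(t₁)e^{λt₁}/λ` with assumed
     effective half-lives (neck uptake 68 h; parotid 9.3 h,
     submandibular 8.6 h; or the patient's own whole-body half-life);
   * 1–2-component whole-body retention fits anchored to A₀, with
     automatic fallback to one component.
4. **Voxel dosimetry** (`iodose.voxdose`) — dose-rate maps by voxel
   S-value kernel convolution (charged-particle only; local-deposition
   kernel by default), mass-averaged VOI dose rates, and their
   mono-exponential time integral.
5. **Whole-body dose** (`iodose.wbdose`) — MIRD formalism with the
   mass-adjusted S-factor `S_WB = 1.34×10⁻⁴ · m_p^{-0.921}` Gy MBq⁻¹ h⁻¹,
   a surrogate for the bone-marrow dose.
6. **Cohort reporting** (`iodose.cohort`) — median (range) of doses per
   administered activity (mGy/MBq) per organ and centre, with exact
   small-sample Mann–Whitney comparisons between activity and stimulation
   groups.

Because clinical images from such studies are not publicly deposited, the
package ships a first-class synthetic-data module (`iodose.synthdata`):
digital phantoms with geometric organs of known activity and effective
half-life, SPECT-like series with Gaussian resolution blur and Poisson
noise, bi-exponential whole-body retention curves, and calibration/sphere
acquisitions — every dataset carries machine-readable ground truth, so the
whole chain is verifiable end to end.

## Worked example

```python
from iodose import (AcquisitionSpec, default_phantom_spec, make_phantom,
                    organ_doses_from_phantom)

phantom = make_phantom(default_phantom_spec())          # six organs, known truth
acq = AcquisitionSpec(times_h=(24, 48, 96), calibration_factor_cps_per_mbq=5000)
results = organ_doses_from_phantom(phantom, acq, a0_mbq=3700.0)
for organ, res in results.items():
    print(organ, f"{res.record.dose_gy:.4f} Gy",
          f"{res.record.dose_per_admin_mgy_per_mbq:.4f} mGy/MBq")
```

prints (noise-free, local-deposition dosimetry):

```
neck_uptake 5.4315 Gy 1.4680 mGy/MBq
salivary_glands 0.2971 Gy 0.0803 mGy/MBq
lung_left 0.2130 Gy 0.0576 mGy/MBq
lung_right 0.2130 Gy 0.0576 mGy/MBq
liver 0.0575 Gy 0.0155 mGy/MBq
spleen 0.0288 Gy 0.0078 mGy/MBq
```

Each dose is the time integral of the organ's mass-averaged dose rate; on
noise-free mono-exponential phantoms it reproduces the analytic ground truth
`Ã · Δ / m` to machine precision. The `examples/` directory walks through
each capability: phantom generation and quantification, calibration and
recovery curves, the three TIAC routes, whole-body dose, and the cohort
report.

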