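# mlcsim

Fluence modeling, planar gamma analysis and parameter commissioning for a
step-function rounded-leaf-end MLC model, driven entirely by synthetic
measurements with known ground truth.

## Who this is for

Medical physicists and researchers who want a desk-scale, fully reproducible
sandbox for the commissioning workflow used with treatment planning systems
that parameterize the multileaf collimator (MLC) by a *leaf-tip width*, an
*average transmission factor* and a *tongue-and-groove width* (instead of a
dosimetric leaf gap or a tip radius). Every "measurement" the workflow
consumes — the vendor leaf-offset table, ion-chamber scans of MLC-defined
fields, diode-array planar QA of step-and-shoot IMRT plans — is generated by
the package from a known machine truth, so parameter-recovery claims are
testable end to end without any hardware data.

## The model

Leaf travel is along `x` (cm, isocenter plane). Planned leaf positions are
leaf-*end* positions `x_end`; the leaf-*tip* position used for fluence is

```
x_tip = x_end + offset + Gain · x_end + Curvature · x_end²
```

with the three coefficients fitted by least squares to a vendor table of
geometric offsets (−20 … +20 cm in 1 cm steps). Relative fluence through a
leaf pair is a step function: 1 between opposing tips, `√T` in a band of
width `w_tip` on the blocked side of each tip (the rounded end modeled as
half the leaf thickness), and the average transmission `T` deeper under the
leaf. Tongue-and-groove is modeled as `√T` bands of width `w_TG` along
cross-leaf boundaries, only where a leaf edge forms the aperture periphery.
A two-Gaussian pencil kernel turns fluence into planar dose; agreement
between calculated and "measured" dose is scored with the 2D gamma index
(global or local normalization, 10% low-dose threshold), verified against an
exhaustive brute-force oracle.

Commissioning runs in a fixed order of decreasing independence: offset fit →
leaf-tip width (FWHM of transverse profiles, penumbra RMSE as tie-break) →
average transmission (mean 2%/2 mm global passing rate over a candidate
grid) → tongue-and-groove width (same objective; ties break to the smallest
candidate).

## Worked example

```python
from mlcsim import (CommissionConfig, MachineTruth,
                    make_commissioning_dataset, run_commissioning)

dataset = make_commissioning_dataset(MachineTruth(), seed=7)
report = run_commissioning(CommissionConfig(seed=7), dataset)

print("offset fit: curvature =", round(report.offset_model.curvature, 6),
      "/cm, R^2 =", round(report.offset_r_squared, 6))
p = report.parameters
print(f"selected: leaf_tip_width = {p.leaf_tip_width} cm, "
      f"transmission = {p.transmission*100:.1f}%, tng_width = {p.tng_width} cm")
col = (report.transmission_table
       .query("criteria == '2%/2mm global'")
       .groupby("transmission")["passing_rate_pct"].mean())
print("mean 2%/2mm passing rate vs candidate transmission:")
for t, r in col.items():
    print(f"  {t*100:4.1f}%  ->  {r:5.1f}%")
```

prints

```
offset fit: curvature = 0.0008 /cm, R^2 = 1.0
selected: leaf_tip_width = 0.3 cm, transmission = 2.5%, tng_width = 0.05 cm
mean 2%/2mm passing rate vs candidate transmission:
   1.6%  ->   86.2%
   1.8%  ->   93.5%
   2.0%  ->   98.1%
   2.5%  ->   99.9%
   3.0%  ->   99.2%
```

The dataset was generated with truth (curvature 0.0008 /cm, tip width
0.3 cm, transmission 2.5%, T&G 0.05 cm) and 1% measurement noise; the
workflow recovers all four from the synthetic measurements alone. The
passing-rate column rises toward the true transmission and falls slightly
past it — the shape on which the selection rests.

A command-line surface mirrors the library
(`mlcsim simulate | fit-offset | fluence | dose | gamma | commission |
report`); try `mlcsim --version` or
`mlcsim gamma ref.csv eval.csv --dd 3 --dta 3 --norm global`.

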