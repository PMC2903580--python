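# lvstrain

Full 3D Green–Lagrange strain of the left-ventricular myocardium from a
**single slice** of 3D displacement data.

Displacement-encoded cardiac MR (e.g. DENSE) measures the 3D Lagrangian
displacement **u**(X, t) of every myocardial pixel on an image slice.
Regional strain follows from the deformation gradient

    F_ij = ∂x_i/∂X_j,   x = X + u,   E = (FᵀF − I)/2,

but a single slice provides almost no spread of reference points along
the slice normal, so the third column of F is near-singular and the
through-plane strains are conventionally obtained from a second,
parallel slice — doubling the scan time. `lvstrain` implements an
analytical single-slice reconstruction that recovers the complete
tensor using three physical constraints:

1. **Incompressibility** — myocardial volume fluctuates by only ~1 %,
   so det F = 1 is enforced on the third column;
2. **Forward/inverse combination** — the inverse-map tensor G
   (deformed → reference) is estimated independently; under det G = 1
   the in-plane adjugate of G yields F₃₃, and the orthogonality of the
   columns of F to the rows of G yields candidate F₁₃, F₂₃ (the
   candidate with the smaller |E₁₃| + |E₂₃| is kept, since out-of-plane
   errors bias those shears upward);
3. **Semi-symmetric torsion** — LV rotation about the long axis is
   nearly independent of azimuth, so on long-axis slices F₁₃ and F₂₃
   are pre-estimated from the out-of-plane displacement divided by the
   distance to the axis.

Strain is reported in local **R**adial / **C**ircumferential /
**L**ongitudinal components, with the noise-sensitive out-of-plane
normal strain replaced by an in-plane area-ratio estimate averaged over
the F- and G-derived principal stretches.

The package ships:

- an **analytical motion phantom**: an exactly incompressible,
  axisymmetric contracting + twisting LV wall (det F = 1 to machine
  precision in closed form) for validation;
- the **single-slice estimator** (`estimate_single_slice`,
  `single_slice_strain`) with displacement pre-processing (phase
  unwrapping, phase→displacement, plus-median and temporal-Fourier
  smoothing) and strain post-filtering (2-SD outlier voiding, |E| > 1
  elimination, median + 1 cm² moving-average smoothing, regional peak
  summaries);
- the conventional **two-slice estimator** and Bland–Altman agreement
  statistics as the reference method;
- experiment runners that reproduce the phantom validation tables.

Intended users: researchers in cardiac MR image analysis and
cardiovascular biomechanics who need full 3D strain from reduced
acquisitions, or a controlled phantom to benchmark strain pipelines.

## Worked example

```python
from lvstrain import run_table_1_2

rep_f, rep_e = run_table_1_2(area_mm2=25.0)
print(rep_e.table.round(4).to_string(index=False))
```

prints (noise-free phantom long-axis slice, 1 mm sampling, 25 mm²
smoothing area, peak contraction):

```
component  variation_magnitude  rms_error  relative_rms
     E_RL               0.1342     0.0433        0.3229
     E_LC               0.0409     0.0017        0.0411
     E_RC               0.0000     0.0017           NaN
     E_RR               0.2965     0.0381        0.1284
     E_LL               0.1771     0.0118        0.0667
     E_CC               0.0688     0.0263        0.3831
```

Every strain component is recovered with an RMS error below 0.05.
`variation_magnitude` is the RMS of the analytic component (its
departure from the identity for tensor elements), `rms_error` the RMS
of estimate − truth over the 924 myocardial pixels, and their ratio the
relative error. The largest error sits in the in-plane shear E_RL,
driven by the deliberately fast transmural variation of ∂u_z/∂R in the
phantom that the 25 mm² least-squares neighborhood smooths; E_RC is
analytically zero, so its 0.0017 RMS is pure estimator residue.
`examples/` contains one short script per capability (phantom, strain
estimation, two-slice comparison, noise sweep, phase pre-processing);
a thin CLI (`lvstrain simulate|estimate|compare|validate`) wraps the
same runners for shell use.

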