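# pericav

Paired fluid-cavity brain-slice simulations: does a CSF-filled ventricular
cavity make the tissue next to it more vulnerable during a head impact?

The hippocampus lies directly beneath the temporal horn of the lateral
ventricle, a thin cavity filled with cerebrospinal fluid (CSF). Because a
liquid transmits compression but essentially no shear, the mechanical
environment of tissue bordering such a cavity differs qualitatively from
tissue embedded in solid parenchyma. `pericav` tests that mechanism with a
desk-scale computational experiment: an idealized 2D plane-strain brain
slice is simulated twice under identical impulsive head loadings — once
with a crescent-shaped cavity treated as coupled CSF (the "TH"
configuration) and once with the same elements assigned brain material
(the "NTH" configuration) — and regional deformation metrics are compared
pairwise.

## What is inside

- **Synthetic paired geometry** (`pericav.geometry`): an annular coronal
  slice with a boundary-fitted crescent cavity calibrated to the
  anatomical temporal-horn/brain volume ratio of 0.13%, labeled bands
  emulating the hippocampal subfields (CA1, CA2/3, CA4/DG, tail,
  subiculum, presubiculum), amygdala and ventral-diencephalon analogs,
  and a distal control band. The TH and NTH meshes are
  node-for-node identical and differ only in element material.
- **Impulsive loading** (`pericav.loading`): haversine pulses whose peak
  translational (g) and rotational (krad/s²) magnitudes default to six
  published video-confirmed football impacts (106.1 g / 12.95 krad/s²
  down to 20.4 g / 4.14 krad/s²), applied as fictitious forces in the
  skull-fixed frame.
- **Materials** (`pericav.materials`): the CSF as a Grüneisen
  (shock-Hugoniot) equation of state,

      P = ρ₀C²μ [1 + (1 − γ₀/2)μ − (a/2)μ²] /
          [1 − (S₁−1)μ − S₂μ²/(μ+1) − S₃μ³/(μ+1)²]²,   μ = ρ/ρ₀ − 1,

  with ρ₀ = 1000 kg/m³, C = 1482.9 m/s, S₁ = 2.10, S₂ = −0.17,
  S₃ = 0.01, γ₀ = 1.2, a Newtonian deviatoric law σᵥ = γ ε̇′ with
  γ = 1 mPa·s, and a −22 MPa cut-off pressure emulating cavitation; the
  brain as a nearly incompressible neo-Hookean solid with one-term Prony
  shear relaxation.
- **Solvers**: an explicit central-difference finite-element solver for
  the solid (`pericav.solid`, fully integrated quads, numba-accelerated)
  and a multi-material arbitrary Lagrangian-Eulerian grid for the cavity
  CSF and its void halo (`pericav.fluid`), advected by a conservative,
  monotone, second-order van Leer (MUSCL) remap.
- **Interface coupling** (`pericav.coupling`): penalty springs on the
  wall/interface separation transmitting normal tension and compression
  while permitting free tangential slip, backed by a smooth moving-wall
  penalization of the fluid and pressure tractions on the wall.
- **Injury metrics** (`pericav.metrics`): first principal Green-Lagrange
  strain E = (FᵀF − I)/2, first principal rate of deformation
  D = (L + Lᵀ)/2, Tresca maximum shear stress, element-wise temporal
  peaks, regional 95th percentiles, and threshold-exceedance area
  fractions (strain > 0.2, rate > 30 s⁻¹).
- **Paired statistics** (`pericav.stats`): percent differences with the
  NTH model as reference, median (Q1, Q3) summaries, and the Wilcoxon
  matched-pairs signed-rank test in the normal approximation without
  continuity or tie correction (at N = 6, all-positive differences give
  p = 0.028).
- **Pipeline** (`pericav.pipeline`) and a thin CLI (`pericav generate /
  simulate / run / report`).

## A worked example

```bash
python examples/02_csf_material_model.py
```

prints

```
reference sound speed: 1482.9 m/s
  mu = +0.0010  ->  P =   +2.2047 MPa
  mu = -0.0150  ->  P =  -22.0000 MPa  <- clamped at the cavitation cut-off
shear stress at a 50 1/s deviatoric rate: 50.00 mPa
```

i.e. the modeled CSF is acoustically stiff (2.2 MPa from a 0.1% density
excess, sound speed equal to the Hugoniot intercept), cannot sustain
tension beyond the cavitation cut-off, and is mechanically shear-free at
impact strain rates — the combination that underlies the cavity
mechanism. The paired demonstration,

```bash
python examples/04_paired_impact_demo.py    # several minutes
```

runs both models under the 106.1 g / 12.95 krad/s² impact and reports,
per ROI, the 95th-percentile strain and strain-rate peaks of both models
with their percent differences: the hippocampal-subfield bands adjacent
to the cavity show strain elevations of tens to hundreds of percent, the
fluid cavity carries < 100 Pa of shear stress while its solid substitute
carries several hundred, and the distal control band changes by well
under 5% in strain. `examples/05_paired_statistics.py` shows the
across-case statistics table on illustrative data.

## Scope

This is a mechanism study at desk scale, not a predictive head model: 2D
plane strain, idealized geometry, a rigid outer boundary, and a softened
bulk modulus. `docs/methods.md` documents the model, its numerical
choices, and what the synthetic setting does and does not show about real
heads.
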