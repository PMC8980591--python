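# Methods

## The experiment

`pericav` implements a paired computational experiment on an idealized 2D
brain slice. Two finite-element models share every node, element, ROI
label, and loading; they differ in exactly one thing: a thin crescent
cavity near mid-radius is either CSF coupled to the tissue through a
fluid-structure interface (the "TH" model) or filled with the same
viscoelastic parenchyma as its surroundings (the "NTH" model). Because the
pair is otherwise identical, any difference in regional deformation is
attributable to the fluid nature of the cavity. The comparison arithmetic
(percent differences with NTH as reference, region-wise 95th-percentile
peaks, matched-pairs signed-rank tests across load cases) mirrors how such
paired simulation studies are analyzed.

## Geometry

The slice is an annulus: outer radius 70 mm (rigid skull boundary), inner
radius 12 mm (a central ventricular opening, free boundary, which also
removes the polar-mesh singularity). The cavity is an annular sector at
center radius 32 mm, thickness 1.35 mm, angular extent 0.45 rad; these
defaults put the cavity/brain area ratio at 0.1303%, within the 0.1-0.3%
anatomical range for the temporal horn and within 0.3% of the 0.13%
calibration value. The structured polar mesh is boundary-fitted: cavity
edges, ROI band edges, and subfield boundaries all lie on grid lines, so
the area ratio is a property of the geometry, not the resolution (a 2x
refinement changes it by < 0.1% relative).

ROI bands: six equal angular slices of a 2.7 mm band hugging the cavity's
concave border stand in for the hippocampal subfields (the temporal horn
forms the roof of the hippocampus); an "amygdala" band sits at the
anterior cavity tip, a "ventral DC" band one band-width medially, and a
distal control band sits diametrically opposite, thousands of cavity
widths away along tissue paths. These are labeled bands, not anatomical
shapes; they give each subfield a well-defined element population for
percentile statistics.

## Loading

Only the peak magnitudes of the six reference impacts are available
(106.1 g / 12.95 krad/s² down to 20.4 g / 4.14 krad/s²), so the waveform
is a free modeling choice: a haversine pulse of 10 ms, a typical football
impact duration, with the translational peak applied along a configurable
in-plane direction and the rotational peak about the out-of-plane axis.
The skull is rigid and the simulation runs in the skull-fixed frame; the
impact enters as the fictitious acceleration field
−a(t) − α(t)×r − ω(t)×(ω(t)×r) applied to solid and fluid alike. The
simulated window equals the pulse (10 ms): the injury metrics are
temporal peaks, which occur during loading, and extending into free
ring-down only accumulates reverberation in a closed, perfectly
reflecting 2D disk.

## Materials

CSF (Table constants): Grüneisen ratio-form equation of state with
ρ₀ = 1000 kg/m³, C = 1482.9 m/s, S₁ = 2.10, S₂ = −0.17, S₃ = 0.01,
γ₀ = 1.2, a = 0. The printed "γ2" in the numerator is read as γ₀
(the standard form), the bracketed S-polynomial divides and is squared
(the standard explicit-dynamics convention; this reading reproduces
2.2047 MPa at μ = 10⁻³, agreeing with the acoustic limit ρ₀C²μ to 0.3%),
tension follows the linearized branch, and the result is clamped at the
cut-off pressure P_C = −22 MPa (cavitation: no sustained large tension).
The deviatoric law is implemented exactly as printed, σᵥ = γ ε̇′ with
γ = 1 mPa·s; the conventional factor-2 form is available behind a flag,
and at this viscosity the difference is dynamically irrelevant.

Brain: deviatoric neo-Hookean with a one-term Prony series,
G(t) = G∞ + (G₀ − G∞)e^(−t/τ), G₀ = 2.2 kPa, G∞ = 1.0 kPa, τ = 10 ms,
and volumetric response K·ln(J)/J with K = 50 MPa. K is softened by
~40x relative to true near-incompressibility to keep the explicit
dilatational time step tractable; K/G₀ ≈ 23000 still enforces effective
incompressibility at tissue scale. A stiffer variant (G₀ = 10 kPa) was
evaluated and rejected: it moves a global shear resonance of the annulus
into the pulse's excitation band, which inflates the no-cavity response
and obscures the paired contrast that is the point of the experiment.

## Solid solver

Explicit central differences on fully integrated (2x2 Gauss) bilinear
quads in plane strain, lumped mass, internal forces from the first
Piola stress P = JσF⁻ᵀ contracted with reference shape-function
gradients. Full integration avoids hourglass-control machinery at the
cost of mild locking, acceptable at this scale. The stable step is
0.5·min(h/c_dil) with h = element area over longest edge, recomputed
every 25 steps on the deformed configuration (compressing cavity-tip
elements shrink their own stability limit; the adaptive step floors at
1/16 of the reference value). Numerical damping: linear bulk viscosity
(coefficient 0.15, as explicit FE codes apply by default) and a small
Newtonian shear viscosity of 0.03 Pa·s. The latter matters because the
Prony branch's loss peak sits at 1/τ = 100 Hz and leaves element-scale
(10-100 kHz) modes undamped; 0.03 Pa·s is near-critical for those modes
while contributing a loss tangent of order 10⁻² at the 100 Hz-1 kHz
frequencies that carry the physics. The kernels are numba-jitted with a
pure-numpy reference path kept under test.

## Fluid solver

A structured Cartesian grid covers the cavity plus a "void mesh" halo
into which CSF may flow. Cells carry CSF mass, CSF volume, and void
volume; velocities are face-staggered (MAC). Each step splits into a
Lagrangian force phase (pressure gradient with compression-only quadratic
and symmetric linear artificial viscosity, the small Newtonian shear
term, coupling forces) and a direction-split, flux-form van Leer (MUSCL)
remap of mass, material volumes, and face momentum, alternating sweep
order per step. The remap is conservative to round-off, monotone, and
exact on linear data. Volume fractions are recovered by renormalizing the
advected material volumes (so vf_csf + vf_void = 1 identically), followed
by a void-collapse closure: net cell compression crushes the pressureless
void before it compresses CSF. Without that closure, compression against
the wall accumulates over-filled interface cells that detonate the stiff
EOS the moment they register as full. Mixed cells cannot sustain tension
(free surface); full cells follow the clamped EOS. Faces carrying almost
no fluid use a mass floor of 0.25ρ₀ in the momentum update and recovery
("flotsam" control). The measured acoustic front speed of a 1D column
converges to C from above (+1.6% at 800 cells), the residual being front
dispersion of the single-cell initial pulse.

## Interface coupling

Three cooperating pieces, applied identically in every run:

1. **Moving-wall penalization.** Every fluid face carries a solid
   occupancy χ ∈ [0, 1], computed as a smoothed signed distance to the
   current wall polyline (linear over one cell width), toward whose local
   wall velocity the face velocity is implicitly relaxed with a time
   constant of two acoustic cell times. This is the Brinkman/immersed-
   boundary treatment of a moving container: it seals the interface
   against advective leakage and, because χ varies continuously with wall
   position, introduces no discrete switching noise.
2. **Pressure traction.** The fluid pressure, sampled just inside the
   cavity and low-passed with a 20 μs moving average (the cavity acoustic
   transit time), loads the wall segments along their normals. The
   rationale for the filter: the tissue beyond the interface is
   acoustically matched to CSF, so a physical wall transmits the mean
   load rather than reflecting and re-radiating the cavity's internal
   ringing, which a stiff closed numerical box otherwise sustains.
3. **Contour penalty.** The signed separation between each wall segment
   and the vf = 0.5 iso-contour (reconstructed linearly along the
   segment normal, baseline-calibrated at t = 0 to remove the sub-cell
   bias of the discretized initial fraction field) generates a restoring
   force k·penetration·length with both signs — tension and compression —
   and zero tangential component, plus a small dashpot on the normal
   relative velocity. With the wall BC carrying the bulk coupling the
   penalty acts as a residual-separation corrector: its stiffness is
   10⁻⁴ of the fluid bulk scale, offsets inside half a cell (below the
   contour's own resolution) are ignored, and the combined traction is
   capped at 20 kPa. A bulk-scale stiffness — the textbook default —
   was tried first and rejected: at three cells across the cavity it
   amplifies micron-scale contour quantization noise into forces that
   crush the adjacent soft tissue.

All interface forces on the solid pass through the same 20 μs low-pass.
Total interface force pairs are equal and opposite by construction; CSF
mass is conserved to round-off over full runs.

## Metrics and statistics

Element-wise strain is the largest eigenvalue of E = (FᵀF − I)/2 and
strain rate the largest eigenvalue of D = (L + Lᵀ)/2, both in the
plane-strain 3x3 embedding; shear stress is Tresca. Peaks are running
maxima over output samples taken every 0.1 ms; regional summaries are
count-based 95th percentiles with linear interpolation between closest
ranks (area weighting is available behind a flag), plus area fractions
exceeding strain 0.2 and rate 30 s⁻¹. The signed-rank test deliberately
uses the normal approximation without continuity or tie correction — the
convention decoded from the published p-values (0.028 for six positive
differences, where exact enumeration gives 0.031) — with exact
enumeration available for n ≤ 12; no multiple-comparison correction is
applied, matching the source analysis.

## What the demo shows, and its limits

Under the default single-case demonstration (the 106.1 g impact), the
paired run reproduces the mechanism: every peri-cavity band shows
strictly larger 95th-percentile strain and strain-rate peaks with the
fluid cavity (hippocampal union strain 0.42 vs 0.10; subfield strain
elevations between ~+20% and ~+530%), the fluid cavity's shear stress
stays under ~10 Pa while the solid substitute carries several hundred Pa
(the < 100 Pa vs > 1000 Pa contrast of the full-scale study, compressed
by the 2D scale), and the distal control band's strain changes by well
under 5%.

Known limitations, all consequences of the 2D desk-scale idealization:

- **Magnitudes are not predictions.** Peri-cavity strain amplifications
  here reach several hundred percent, versus tens of percent at full
  scale: a plane-strain cavity is effectively an infinite slot that
  severs all out-of-plane load paths, so it perturbs its surroundings
  far more strongly than a finite 3D pocket of the same volume fraction.
  Only the sign and ordering of the paired contrast transport.
- **The distal strain-rate comparison does not transport.** Spectral
  analysis of the distal signals shows both models dominated by the
  global ~124 Hz shear mode of the annulus and its harmonics; the slot
  perturbs these global mode amplitudes at first order, leaving a
  ~+50% TH excess in distal rate while distal strain agrees to < 1%.
  The full-scale claim that distant regions change by < 5% in both
  metrics is recoverable only in 3D; here the distal consistency check
  is therefore stated for strain.
- The skull is rigid and the subarachnoid space absent, so the slice is
  perfectly reverberant; absolute strain-rate levels depend on the
  numerical dissipation settings more than strain levels do.
- The softened bulk modulus slows dilatational waves by ~7x; pressure
  transients are qualitative.
- The synthetic ROI bands have 9-42 elements; their 95th percentiles are
  close to band maxima and correspondingly noisy compared with the
  thousands-of-elements subfields of a full head model.
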