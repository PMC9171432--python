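# Methods

## Scope and model

`mechanoct` quantifies the mechano-regulation of bone remodeling from
time-lapse micro-CT: given registered longitudinal mineral-density volumes of
a healing (or adapting) bone and the applied loads, it asks whether the local
mechanical environment predicts where bone will form, stay quiescent, or be
resorbed over the following interval. The pipeline is

1. **Pre-processing** — Gaussian filtration (default σ = 1.2 voxels with a
   truncated support of 1 voxel, i.e. a 3×3×3 kernel) followed by
   multi-density binning into bands of 25 mg HA/cm³ from 395 (the
   bone/soft-tissue boundary) to 720 mg HA/cm³. Band intervals are half-open
   `[edge_k, edge_{k+1})` with the top band closed at (and above) its upper
   edge; the convention is fixed so that thresholding a binned image at a
   band edge is identical to thresholding the filtered image directly.
2. **Masking** — the original cortex is thresholded at 645 mg HA/cm³ on the
   baseline (week-0) image; the medullary cavity is recovered per transverse
   slice by radial ray casting (a voxel is medullary when rays in all sampled
   transverse directions hit closed cortex); everything else is peripheral.
   Masks are static over the series, as they derive from baseline only.
3. **Micro-FE** — each voxel becomes an 8-node hexahedral element with
   trilinear shape functions and isotropic linear elasticity. Soft tissue
   (band 0) receives E = 0.003 GPa; bone bands map through a configurable
   monotone density→modulus ramp; the medullary cavity is capped by a
   20 GPa plate at the top of the mesh to suppress soft-tissue edge effects.
   Two displacement-controlled cases are solved: uniaxial (1 % compressive
   displacement of the top slice, bottom slice fixed axially) and bending
   (top-slice axial displacement linear in the signed distance from a
   bending axis through the density-weighted in-plane centre of mass,
   reaching 1 % of mesh height at the furthest in-plane edge). Solutions are
   rescaled to the in vivo load by applied/resultant (strain and displacement
   linearly, strain energy density quadratically) and superposed at the
   displacement level; SED `U` and effective strain `ε = sqrt(2U/E)` are then
   evaluated per element from the combined field.
4. **Remodeling classification** — the binary difference of the bone masks
   (density ≥ 395 mg HA/cm³) between consecutive time points labels each
   voxel formation / quiescence / resorption / background. Quiescent voxels
   whose density band strictly increased are flagged as mineralization
   events. Band decreases at quiescent voxels are retained in the band
   channels but are not resorption, which is binary presence only.
5. **Mechano-regulation statistics** — for every interval, each eligible
   surface voxel (soft tissue face-adjacent to bone, or bone with a non-bone
   face neighbour) contributes one row with its region, density band, its
   normalized effective strain at the interval's *start* (stimulus precedes
   response) and the observed event. Strain is normalized to the 99th
   percentile over the whole simulation region (excluding the cap plate), so
   about 1 % of voxels exceed 1. Readouts: conditional event probabilities
   per strain bin; ROC AUC of strain as a score for formation and (among
   quiescent bone voxels) mineralization; and a two-threshold sweep in which
   strain ≥ upper threshold predicts formation, ≤ lower threshold predicts
   resorption, and in between quiescence. The correct classification rate
   (CCR) is the unweighted mean of the three per-class recalls (balanced
   accuracy), so its chance level is exactly 1/3 regardless of class
   imbalance; at the degenerate threshold pair (0, 0) the formation rule
   wins and the CCR is exactly 1/3.

The statistics stage is exposed statsmodels-style:
`MechanoregulationModel(table).fit()` returns a results object holding the
probability curves, the AUCs with Hanley–McNeil standard errors and the CCR
matrix, with a `summary()` text table; the underlying functions remain
available for direct use.

## Parameters that matter

| parameter | default | units | notes |
|---|---|---|---|
| voxel size | 10.5 | µm | isotropic; configurable per image |
| filter σ / support | 1.2 / 1 | voxels | truncated Gaussian pre-filter |
| band edges | 395…720 step 25 | mg HA/cm³ | first edge = bone boundary |
| cortex threshold | 645 | mg HA/cm³ | baseline cortical mask |
| soft-tissue modulus | 0.003 | GPa | all band-0 voxels |
| plate modulus / thickness | 20 / 2 | GPa / slices | cap over medullary cavity |
| density→modulus ramp | 4→15 linear | GPa | over 395→720 mg HA/cm³; the original study's law is not published, so the ramp is configuration |
| Poisson ratio | 0.3 | — | uniform, standard in micro-FE bone work |
| applied strain fraction | 0.01 | — | both load cases |
| moment arm | 10 | mm | fixator pin length; bending moment = machine force × arm |
| load schedule | 8→16 N ramp (loaded), 10 N uniaxial (control) | N | per time point |
| CG tolerance / cap | 1e-6 / 20·√DOF | relative residual | Jacobi-preconditioned conjugate gradients |
| n_bins | 50 (+ overflow) | — | 2 % of maximum strain per bin |
| n_grid | 100 | — | per axis of the CCR threshold sweep |

## Numerical choices

* The stated boundary conditions (axial-only constraints on both end
  slices) leave in-plane translation and axial rotation singular; they are
  removed by pinning ux, uy at one bottom corner and uy at a second corner
  offset in x — the minimal constraint set, perturbing the stress field
  least.
* Element SED is evaluated at the element centroid (single-point strain);
  per-voxel scalars are what the statistics consume.
* The bending resultant is measured as a moment (axial reactions × signed
  lever arms about the bending axis) and scaled against machine force ×
  moment arm, which is dimensionally consistent with the lever-arm
  construction of the applied load.
* SED rescales with the square of the force ratio, as linear elasticity
  requires.
* Superposition recomputes the strain tensor from the summed displacement
  field — scalar effective strains are *not* additive.
* Empty strain-bin entries are NaN, never interpolated; probability
  normalization is exact at the count level (each surface row falls in
  exactly one event class of its bin), with float ratios summing to 1
  within one ulp.
* CCR cells with lower threshold > upper threshold are undefined (NaN) and
  excluded from the maximum; classes absent from a stratum are excluded
  from the recall mean.
* AUC ties use the midpoint-rank (Mann–Whitney) convention; single-class
  strata report a missing AUC rather than a value.

## The synthetic phantom

No imaging data are bundled, so every stage is exercised on a synthetic
longitudinal phantom: a hollow-cylinder cortical diaphysis (720 mg HA/cm³,
above the cortical threshold) with a fully transverse defect gap, soft
tissue at 120 mg HA/cm³ elsewhere. Weekly remodeling events are sampled
from a known mechanostat: formation probability monotone non-decreasing and
resorption probability monotone non-increasing in normalized effective
strain, with surviving bone mineralizing by 25 mg HA/cm³ (one band) per
week up to 720. New bone appears at 395 mg HA/cm³, the lowest analysis
band. Remodeling acts only on surfaces (6-connectivity), so no voxel can
form and resorb in the same step. Additive Gaussian noise (default sd
15 mg HA/cm³, clipped at zero — small against the 25 mg HA/cm³ band width,
of the order of calibrated micro-CT noise after reconstruction) is applied
only to the emitted images; the internal state and the ground-truth log are
noise-free, which is what makes event-for-event reproduction testable.

The default logistic mechanostat (formation: maximum 0.6/week, slope 10,
midpoint 0.3; resorption: maximum 0.3/week, slope 30, midpoint 0.1) was
placed, once, where the phantom's solved strain distribution is active:
with normalization to the region-wide 99th percentile, soft tissue in and
near the defect gap sits high on the strain axis (so the gap bridges over a
few weeks) while bone surfaces sit low (so unloaded bone remodels away
slowly, ~1–2 %/week at zero strain). These are generator properties chosen
for a plausible healing trajectory, not fitted quantities.

What the phantom does **not** emulate: anatomical femur geometry, the
biological phases of healing (inflammation, vascularization, endochondral
ossification), fixator compliance, registration error, beam hardening, or
partial-volume calibration effects. One partial-volume-like effect *is*
present and worth knowing about: newly formed voxels enter at exactly the
395 mg HA/cm³ boundary, so the Gaussian pre-filter pulls single-voxel
formations below threshold and the filtered analysis detects only a subset
of generated formation events. Detected events still carry the generative
strain dependence — which is what the statistics measure — but absolute
formation rates from the filtered path understate the generated ones.
Passing tests therefore demonstrate correctness of the machinery and
recoverability of a known mechanostat, not biological fidelity.

## Problem sizes and runtimes

The test suite and the acceptance script run on two phantom scales chosen as
the package's reference problems: a 20³ "tiny" phantom (end-to-end in
seconds) and a 40×40×60 "small" phantom over 3 weekly time points
(≈ 300 k degrees of freedom per FE solve; the full simulate-and-analyse
cycle takes a few minutes on one CPU). The FE solver converges in a few
hundred CG iterations at these scales despite the ~5000:1 stiffness
contrast between cortical bone and soft tissue. Larger images (the
300×300×180 subvolumes typical of in vivo studies) are supported by the
same code path but benefit from more iterations and memory; the ray-cast
masking is O(n_dirs · steps) per voxel and is the first candidate for
optimization at that scale.

## Known limitations

* Linear elasticity, static analysis only; no geometric or material
  nonlinearity, no viscoelasticity, no strain amplification by the
  lacunar microstructure.
* The density→modulus law is a configurable placeholder ramp; absolute
  strain magnitudes (and anything derived from them other than rank-based
  statistics) depend on it.
* Masks do not track the callus over time; they derive from baseline.
* Rates are reported as volume per week (voxel count × voxel volume / Δt);
  no areal (surface-normalized) rates are computed.
* The conditional-probability, AUC and CCR readouts are descriptive; no
  inter-group inferential statistics or multiple-testing control are
  provided.
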