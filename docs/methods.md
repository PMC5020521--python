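# Methods

`voxelfe` re-creates, on synthetic data, the computational chain used for
short-term precision studies of micro-finite-element (micro-FE) bone
strength estimates from high-resolution peripheral quantitative CT
(HR-pQCT): image segmentation, three voxel-based FE material models, a
simulated compression test, mechanical outcome measures, and
root-mean-square coefficient-of-variation precision statistics over a
cohort of repeat scans.  Because no deposited scans exist for this kind of
study, the package ships a phantom generator whose paired "baseline" and
"follow-up" scans differ by controlled repositioning, so every stage of
the chain is testable without patient data.

## Synthetic phantoms

A phantom is a cortical tube enclosing a cubic lattice of trabecular
struts, voxelised at the scanner's isotropic 82 μm resolution with
densities in mg HA/cm³:

* cortical shell: outer radius 0.95 mm (default), thickness 0.28 mm,
  density 900 mg HA/cm³ — typical cortical volumetric BMD;
* trabecular struts: 0.164 mm (2-voxel) rods on a 0.6 mm lattice at
  600 mg HA/cm³, clipped one voxel short of the endosteal surface (rods
  running tangent along the shell are not an anatomical feature and are
  unresolvable for any contour algorithm);
* axial structure: a metaphyseal-flare taper (0.04 mm radius per mm,
  wider distally) plus a smooth seeded radius wobble (0.04 mm amplitude,
  ~4-slice correlation length).  Without axial structure a shifted repeat
  scan would be indistinguishable from its baseline and both axial
  registration and the shift→precision-error association would be
  degenerate.

The default phantom is the noise-free ground-truth anatomy
(`background_noise_sd = 0`); scanner noise, in-plane motion and motion
blur belong to the *acquisition* and are applied by `rescan`.  The default
cohort grid is 48×48×110 slices (the standard 9.02 mm region); the
precision study and tests run a scaled-down 32×32×64 grid for tractable
solve times — results there are sign- and magnitude-checks, not
reproductions of cohort tables, which would require real scans.

Geometric caveats the phantom does **not** emulate: plate-like
trabeculae, cortical porosity, marrow inhomogeneity, partial-volume
blur from the scanner point-spread function, and beam-hardening.  A green
test therefore establishes that the pipeline's *mechanics and statistics*
are correct, not that real-bone values are reproduced.

### Repeat scans and cohorts

`rescan` applies, in order: axial slice shift (linear interpolation for
fractional shifts; slices leaving the field of view are filled with
background noise), in-plane rigid rotation/translation, a directional
motion blur whose width scales with a `motion_amplitude` proxy in [0, 1]
(which replaces the manufacturer's visual 5-point grade), and additive
Gaussian noise.  Slice 0 is the distal end; positive shift means the
captured region moved proximally, i.e. `follow[z] = base[z + shift]`.

`generate_cohort` instead voxelises the follow-up at a *shifted axial
window* of the same deterministic phantom geometry: real repositioning
captures new anatomy, whereas background-filled end slices would
disconnect the FE load path.  Per-participant phantom parameters are
drawn from truncated normal distributions; axial shifts are drawn as
integers from the observed per-scan range (−19..17 slices); the scan
interval is ~N(10, 4) days.  All randomness flows from explicit integer
seeds through `numpy.random.SeedSequence` spawning.

### Common-region registration

The axial offset between two scans is estimated by maximising the
normalised cross-correlation of the per-slice bone cross-sectional area
profiles (area = voxels ≥ 400 mg HA/cm³) over integer shifts, mirroring
the scanner's cross-sectional-area registration; the method's similarity
metric is not published, so NCC was chosen as the standard choice for
profile matching.  `common_region_pct = 100 (n_slices − |shift|) /
n_slices`.  Near-ties resolve toward the smaller displacement; a best
score below 0.2 raises a "no plausible overlap" error.

## Segmentation

Bone is density ≥ 400 mg HA/cm³ (inclusive — strictness is a declared
convention).  The periosteal contour is automatic, slice by slice:
morphological closing (radius 3), hole filling, largest 8-connected
component.  The manual contour correction used with the scanner software
is replaced by this automatic pipeline; phantom geometries are designed
so no correction is needed.

The cortical/trabecular split: a small opening (radius 1) strips
strut-scale structures; the opened components connected to the periosteal
surface form the cortex; a closing (radius 2) then annexes intracortical
pores — but only *void* voxels, never bone, so struts abutting the shell
stay trabecular.  Everything inside the resulting endocortical contour is
the trabecular compartment.  Limits: the cortex must be ≥ 3 voxels
(~0.25 mm) thick to survive the opening, and an error is raised when the
shell is discontinuous on more than half the slices.  3-D bone islands
under 27 voxels are removed.  The exact morphological parameters of the
commercial dual-threshold implementation are unpublished; these defaults
are declared, not inferred.

## Finite-element models

Every included voxel becomes an 8-node (trilinear) hexahedral element,
linear-elastic and isotropic, Poisson ratio 0.3, units mm/N/MPa:

| model | element set | Young's modulus |
|-------|-------------|-----------------|
| STM   | bone voxels | 10 GPa (configurable, e.g. 6.829 GPa) |
| DTM   | bone voxels | cortical 20 GPa, trabecular 17 GPa |
| E-BMD | voxels inside the periosteal contour with E above a 1 MPa floor | `E = 15004 (ρ/1200)^1.7` MPa, ρ clamped at 0 |

The E-BMD domain choice (periosteal mask rather than the full scan
cylinder) prevents meshing air around the bone; whether the commercial
implementation masks this way is not published.  Components without a
26-connected load path between the two end slices are removed; node
numbering is lexicographic in (z, y, x).

Boundary conditions simulate a high-friction axial compression at 1 %
strain: the distal face is displaced axially by
`0.01 × n_slices × 0.082 mm` (0.0902 mm for the standard region) with
in-plane motion suppressed; the proximal face is fully fixed.

## Solver

All elements share one geometry, so the global stiffness is one
unit-modulus 24×24 element matrix (full 2×2×2 Gauss integration) scaled
per element and assembled sparse.  Prescribed DOFs are eliminated; the
reduced SPD system is solved with conjugate gradients (Jacobi
preconditioning by default, ILU optional, relative residual 1e-6 against
the load norm).  Reactions are recovered by applying the full stiffness
to the solution and summing axial nodal forces per face.

Per-element strain is the average over the 8 Gauss points (energy-type
quantities are averaged after squaring, i.e. the strain-energy density is
the Gauss-point mean of ½ εᵀCε).  The energy-equivalent strain is
`ε_eq = sqrt(2U/E)` with the element's *own* modulus — the definition
under which doubling a tissue modulus halves the strain limit the tissue
can sustain at equal energy, which is the rationale for the dual-tissue
failure limit below.

## Outcomes

* **Stiffness** (kN/mm): distal axial reaction / applied displacement.
* **Apparent modulus** (MPa): reaction / (CSA × 0.01), with CSA the mean
  periosteal (total) cross-sectional area over slices.  Whether the
  reference implementation uses total or bone-only area is unpublished;
  total area is the default here and configurable by passing a different
  CSA.
* **Average von Mises stress** (MPa): unweighted element mean (equal
  voxel volumes make it the volume-weighted mean).
* **Failure load** (kN), Pistoia-style: by linearity, the solved load is
  scaled by `s* = limit / q` where `q` is the k-th largest per-element
  criterion value, `k = ceil(0.02 N)` (nearest-rank, no interpolation).
  Limits: 7000 με for the single-tissue and density-scaled models,
  3500 με for the dual-tissue model, or 70 MPa energy-equivalent stress
  (`sqrt(2UE)`) for the stress variant — identical to the strain variant
  whenever one modulus is used.
* **Load sharing** (dual-tissue): per transverse element layer, the axial
  force σ_zz·h² is partitioned by tissue; the minimum and maximum
  cortical/trabecular percentages across layers are reported.

## Precision statistics

`CV%_RMS = sqrt((1/m) Σ_j [100 · SD_j / x̄_j]²)` with the two-point
sample SD `|x1 − x2|/√2` (n−1 denominator).  The squared term is the
whole per-participant CV% — the RMS reading of the published formula,
which matches the convention this metric descends from.  CV% samples with
skewness z-score (Fisher g1 over `sqrt(6/n)`) above 1.96 are square-root
transformed.  Model comparison: Friedman omnibus (repeated-measures
ANOVA optional) followed by the three pairwise paired comparisons
(Wilcoxon signed-rank by default, paired t-test optional) with Bonferroni
multiplication ×3 capped at 1.  Covariate screens are Spearman rank
correlations (average ranks on ties) of per-participant CV% against scan
interval, motion amplitude and common region.

## Study pipeline

`run_study` chains the stages for a cohort and writes `outcomes.csv`,
`precision.csv`, `cohort_metadata.csv`, `summary.json` (byte-reproducible
for a fixed config) and a human-readable report.  Participants whose
motion amplitude exceeds a configurable cutoff are excluded before the
precision analysis (mirroring quality-based exclusions), and the study
aborts when more than 20 % of the analysed participants fail a stage.
An optional motion-free control arm re-analyses each baseline against an
identity rescan; identical volumes are served from a content-addressed
cache (the solver is deterministic, so this changes only runtime).

## Numerical choices and degenerate inputs

* Solver tolerance 1e-6 (relative) for studies; 1e-12 in oracle tests.
* Registration floor 0.2 NCC; constant-area profiles raise an error.
* `cv_percent` requires a positive pair mean; identical samples short-
  circuit comparison p-values to 1 (the signed-rank test is undefined on
  all-zero differences).
* Zero-density voxels are excluded from the E-BMD mesh (E = 0 ≤ floor);
  negative densities clamp to 0 before the power law (complex powers).
* The discontinuity check counts slices where the space inside the
  periosteal contour reaches the contour boundary without crossing
  cortex.

## Known limitations

* Phantom meshes are 10³–10⁵ elements; the multi-million-element meshes
  of real scans (and multigrid-scale solvers) are out of scope.
* The lattice phantom's trabecular load share (~2–10 %) is below the
  30–50 % seen in vivo; per-tissue outcome magnitudes are therefore not
  comparable to cohort tables.
* In-plane rotation uses linear interpolation; registration estimates
  integer axial shifts only (fractional shifts appear only as cohort
  averages in the motivating studies).
* The omnibus model-comparison test is delegated to standard routines;
  no multivariate (Wilks/Pillai) machinery is re-derived.
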