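# Methods

## Scope and units

The unit of analysis is one mitotic division of one blastomere in a
cleavage-stage embryo: a closed polygonal outline of the cell's apical
plane (µm), the observed spindle-pole positions in that plane, and labels
(lineage name, embryonic stage, mitotic phase, experimental group).
Angles are *axial* throughout: defined modulo 180°, measured
counter-clockwise from +x; the distance between two axial directions is
the acute angle in [0°, 90°]. All lengths are µm, all times minutes.

## The pulling-force model

Astral microtubules (MTs) are modelled as `n_rays` rays per spindle pole,
equally spaced over 360° in the lab frame, each reaching the cortex and
pulling on its pole with force `f(L) = L^β` where L is the ray length.
The energy of a placement (center **c**, axial angle θ, spindle length ℓ)
is the exact potential of those forces,

    E(c, θ) = Σ_poles Σ_rays φ_β(L),
    φ_β(L) = β/((β−1)(β+1)) · L^{β+1}   (β ≠ 1),
    φ_1(L) = L²(2 ln L − 1)/4           (β = 1, the limit kernel).

φ_β is the ray-sum form of the area integral `c_β ∫∫ |x−p|^{β−1} dA`
over the cell, whose gradient is the summed pull of a uniform astral fan;
consequently `−∇E` is the net force on each pole and `−dE/dθ` is the
mechanical torque on the spindle. Stable placements are energy minima.

Two structural facts about this model family shape the implementation:

- **Centering.** For every 0 < β the potential has an interior minimum,
  so the predicted spindle is centered (at the centroid exactly when
  β = 3, near it otherwise). A formulation that *maximizes* Σ L^{β+1}
  instead is not a potential of the forces and drives the optimizer's
  center to the cell boundary.
- **The critical exponent β = 3.** `Σ L⁴` over a uniform fan equals (up
  to discretization) `∫∫ |x−p|² dA = I_c + A·d²`, which depends only on
  the pole's distance d from the area centroid. At β = 3 the landscape
  therefore carries *no orientation information*; the package computes
  it anyway and flags it degenerate via the relief test. For 0 < β < 3
  the energy minimum lies along the cell's long axis (the Hertwig rule);
  above β = 3 the preference inverts to the short axis. The default
  β = 1 — force proportional to MT length — is the standard force law
  for cortical dynein pulling on astral MTs and sits squarely in the
  long-axis regime. The β = 1 energy involves `ln L`, so absolute
  energies depend on the µm unit; predictions do not, because the extra
  term `ln(s)·ΣL²` under rescaling by s is constant over placements
  (`ΣL² ∝` cell area).

### Parameters

| parameter | default | meaning |
|---|---|---|
| `beta` | 1 | force–length exponent `f = L^β` |
| `n_rays` | 180 | rays per pole over 360° |
| `dtheta` | 1° | orientation grid step |
| `spindle_length_mode` | observed | spindle length from the observed pole separation, or `fraction` |
| `spindle_fraction` | 0.4 | fraction of the major-axis length when no observation exists |
| `center_mode` | optimize | per-orientation center descent, or `centroid` (pinned) |
| `relief_tol` | 0.02 | relative landscape relief below which the prediction is flagged degenerate |

### Placement search

For each θ on the grid the center is descended from the polygon centroid
by a batched pattern search (all orientations in lockstep, every energy
evaluation one compiled ray-cast kernel call); placements with a pole on
or outside the boundary are infeasible (+∞). The winning orientation is
refined by quadratic interpolation, and — in `optimize` mode — the
lowest few local minima of the landscape are each polished by a joint
Nelder–Mead refinement of (c, θ), because near-tied basins can be
misranked at grid resolution. A spindle too long to fit is shrunk
geometrically (×0.85) until a feasible placement exists. Predictions are
deterministic for fixed parameters.

`exhaustive_scan` provides the slow reference: the full product of a
center lattice and a fine orientation grid, optionally polished by pure
grid pattern-descent from every local minimum of the per-orientation
profile (`refine=True`). The test suite requires the fast search to
agree with this scan within 2° and 2% of the major-axis length on random
anisotropic shapes. The comparison fixtures use clearly anisotropic
shapes (aspect ≥ 1.6): for flatter shapes the energy valley is shallower
than the scan's own lattice-quantization noise and the comparison would
measure that noise, not search correctness.

### Discretization

The landscape of a polygonal shape carries an O(1/n²) angular ripple
from the vertex and ray discretizations. With ≥ 192 vertices and the
default 180 rays the induced angle error is a few tenths of a degree;
coarse polygons (≤ 64 vertices) can shift the argmin by 1–2°. Tests that
assert sub-degree angle accuracy on smooth families therefore use
≥ 192-vertex polygons (and denser rays where ±0.5° equivariance is
asserted); the synthetic blastomere default of 48 vertices mimics manual
tracing and is ample for deviation statistics at realistic noise levels.

## Deviation metrics

*Orienting deviation* is the acute angle between the observed and
predicted axes (0–90°). *Centering deviation* is
`100·|c_obs − c_pred| / length_major`: the denominator — the cell's
equivalent-ellipse major-axis length — is a deliberate convention
(so "centered within 20%" reads as within 20% of the cell's long
length) and is the main free choice in this metric; it is raised for
isotropic contours, whose major axis is undefined. Principal axes come
from the second area moments of the filled polygon (robust to uneven
manual-tracing vertex spacing), with lengths of the same-moments
ellipse; shapes whose moment-eigenvalue ratio is below 1.02 are flagged
isotropic.

Clone patterns classify four grand-daughters after two division rounds:
each daughter axis within 45° (axial) of the mother's is an oriented
cell division (OCD); 0/1/2 parallel daughters give square/T/line.
Misorientation incidence is the percent of divisions departing more than
a threshold (default 45°) from the lineage's invariant-pattern reference
axis. Cycle lengthening is `100·(T_curr − T_prev)/T_prev`; asynchrony is
`mean(animal) − mean(vegetal)` mitotic-entry times, positive when the
animal hemisphere enters later.

## 3D shape stage

Meshes are closed triangulated blastomere surfaces with per-face
apical/basolateral labels (geometry via trimesh: OFF/PLY input, sidecar
CSV or PLY integer `label` property for the partition). Sphericity uses
the raw (unsmoothed) mesh and the standard `π^{1/3}(6V)^{2/3}/A` with the
ideal sphere as reference. The apical plane is found among planes
containing the pole–pole axis by scanning the rotation angle at 1° and
refining by golden-section search, scoring each plane by the area
fraction of faces (assigned by centroid side) on the correct side; the
cross-section loop containing both poles becomes the 2D contour, in
plane coordinates with x along the pole axis. Pole-inside-mesh tests use
a generalized winding number (no ray-casting backend required).
A separation score near 0.5 means the labeling carries no planar signal
and triggers a warning.

## Synthetic data

The generators emulate the study's inputs and are pure functions of
(params, seed):

- **Contours** — ellipse, superellipse (exponent 2.2–3), low-order
  Fourier-perturbed ellipse ("blob"), and a flattened (high-aspect)
  variant; defaults: major-axis length 20–40 µm and aspect 1.1–3
  (apical planes of cleavage blastomeres are a few tens of µm and range
  from near-round to strongly elongated), 48 vertices, harmonic noise
  0.05. Invalid polygons are rejection-resampled. The real distribution
  of apical aspect ratios is not tabulated; the range is a modeling
  choice.
- **Observations** — the metaphase axis is the model prediction plus
  wrapped axial Gaussian noise (default sd 15°, which reproduces the
  observed aligned-population statistics: ~50/80/95% of deviations below
  10/20/30°) and isotropic center noise (default 1 µm); a planted subset
  of exactly `round(f·n)` cells (default f = 0) receives a prophase axis
  offset by Uniform(45°, 90°) with random sign — cells that visibly
  rotate into alignment during mitosis, bracketing the prophase
  deviations reported for rotating lineages. Default population size
  n = 149 divisions. Axial wrapped-normal noise folded to [0°, 90°] has
  mean `σ√(2/π)` and MLE `σ̂ = √(mean d²)`, used for recovery checks.
- **Meshes** — icosphere, box, 2:1:1 ellipsoid and 2:2:1 flattened
  kinds; hemisphere, spherical-cap-fraction (closed-form z-cut on the
  sphere, area-quantile otherwise) and random labelings, with the exact
  separating plane recorded where one exists.
- **Timing** — two-hemisphere mitotic-entry times, vegetal ~N(t₀, σ),
  animal ~N(t₀+dt, σ); dt = 15 min emulates the control regime and
  dt = 6–8 min the Wee1-perturbed regime.

What the generators do *not* emulate: real apical surfaces are polygonal
cell–cell interfaces with curvature and neighbor constraints; noise in
real tracings is correlated along the outline; spindle rotation is a
continuous trajectory, not a two-phase offset; and lineage identities
carry real biological covariates. Passing tests therefore demonstrate
the correctness and calibration of the *analysis*, not biological
conclusions about any particular embryo.

## Statistics

Deviations are treated on [0°, 90°] exactly as scored. The null for "no
relation between shape and spindle" is Uniform(0, 90); the one-sample KS
test uses the exact finite-n null for n ≤ 150 (asymptotic above).
Threshold fractions count deviations strictly below 10/20/30°. Group
comparisons: Wilcoxon rank-sum with continuity correction (the
`wilcox.test(correct=TRUE)` convention; the statistic reported is the
Mann–Whitney U) or an unpaired two-tailed pooled-variance t-test.
Per-lineage bars are mean ± s.e.m. No multiple-testing correction is
applied; p-values are raw. Pooled statistics exclude records flagged
degenerate (near-round cells, where the prediction is uninformative) and
the unequal-cleavage germ-line lineages (default B4.1, B5.2, B6.3),
whose spindles are positioned by a cortical structure outside the
geometric model; both exclusions are configurable. By default only
metaphase records enter the pooled distribution (prophase axes may not
yet have rotated into alignment); this is configurable.

## Pipeline and reproducibility

`run_analysis` predicts every record, scores both deviations, and emits
a per-cell table (every input appears exactly once, with status
analyzed / degenerate / skipped), a pooled summary, and a JSON report
whose header carries the package version, a hash of the full
configuration and the seed. All randomness flows through seeded
generators, so identical configurations produce byte-identical outputs.
The mesh stage computes sphericity, apical ratio and the extracted
apical-plane contour per cell, skipping (with a logged reason) meshes
that fail validation.

Problem sizes used by the acceptance script: 150 shape/exponent
combinations for the long-axis sweep, 30 shapes for the search-vs-scan
comparison, a 200-cell synthetic population for noise recovery, and
2000 + 1000 replicates of n = 149 for KS calibration — sizes at which
every check's sampling error is well inside its assertion band.

## Known limitations

- The model is strictly 2D; cells whose spindles respond to cues outside
  the apical-plane geometry (unequal-cleavage germ-line blastomeres,
  fate-asymmetric divisions) are expected to deviate and are handled by
  exclusion, not modelled.
- β ≥ 3 landscapes are computed but orientation-free (β = 3) or
  short-axis (β > 3); the degenerate flag is the guard.
- The apical-plane search scans a one-parameter family (planes through
  the pole axis); labelings not separable by any such plane yield the
  best achievable score with a warning, not an error.
- Energy values are reported in arbitrary units (β-dependent scale);
  only differences and argmins are meaningful.
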