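# Methods

## The screen in brief

A motility-enhancement screen measures, per 384-well plate, the median
curvilinear velocity (VCL) of all sperm tracks in each well — immotile
tracks included — averages the medians of the two imaged positions per
well, and normalizes to the median of the plate's 16 DMSO
vehicle-control wells: `% of control = (VCL median / DMSO median) ×
100`. A compound is a primary hit when its % of control is at least
100 plus a per-library cutoff (20 or 40 percentage points; boundary
inclusive by choice, stated here because the rule is otherwise
ambiguous). Primary hits are re-tested over an 8-point, 3-fold
dilution series from 10 µM in two independent experiments on different
biological material, each fitted with a four-parameter logistic; a
compound is confirmed only if both experiments show a converged
enhancing fit.

## Motion model

Cells follow a 2-D persistent random walk. Per frame interval a cell
takes a step of speed drawn from a class-specific normal distribution
(truncated at zero) scaled by 1/frame_rate, with heading increments
drawn wrapped-normal; the per-step heading correlation
`E[cos Δθ] = exp(−σ²/2)` equals the class's `directional_persistence`.
Isotropic Gaussian localization noise is added to every observed
position. The three classes default to:

| class | speed mean (µm/s) | speed SD | persistence | noise SD (µm) |
|-------|------------------:|---------:|------------:|--------------:|
| IM    | 0                 | 0        | —           | 0.2           |
| NPM   | 35                | 12       | 0.30        | 0.5           |
| PM    | 90                | 20       | 0.98        | 0.5           |

with default class fractions (IM, NPM, PM) = (0.2, 0.2, 0.6) for
density-gradient-prepared donor sperm, where the motile fraction is
high. These are CASA-plausible values chosen once for this package;
no published per-class motion parameters exist to copy. Imaging
defaults to 25 frames/s for 2 s (50 frames) — a CASA-conventional
clip length; the source platform's actual frame rate is not public.
Fields default to 1300 × 1000 µm (a 10× high-throughput microscope
field of view) with 500 cells per field and two fields per well: a
desk-scale stand-in for the ~10,000 cells per well of the full assay,
chosen so a whole plate processes in minutes on one CPU. Per-track
VCL averages ~49 step speeds, so each class's VCL distribution is
much tighter than its per-step speed SD; with a 60% PM fraction the
well median sits inside the PM bulk, which keeps the median's sampling
SD near 2–3% of its value at 500 tracks/field — the regime in which a
20-percentage-point cutoff is a many-sigma event on a null well.

Compound effects are modelled as a four-parameter-logistic activation
`h(c) = 1/(1+(EC50/c)^hill)` (identically zero at c = 0) that scales
NPM and PM speed mean and SD by `1 + (multiplier−1)·h` and can shift
population fraction into PM. Scaling all motile speeds by m scales
the well median by m whenever the median lies in the motile bulk, so
the expected % of control is `100·m(c)` in closed form — what the
plate and dose–response generators and their tests use. Dose–response
responses are generated directly at the summary level: expected % of
control plus additive Gaussian noise (default SD 5 percentage points,
2 replicates per concentration per experiment); no published error
model exists, and additive noise on the normalized scale is the
simplest defensible choice.

What the generator does **not** emulate: hydrodynamics and flagellar
beating, 3-D motion and focus loss, capacitation-state changes,
well-edge effects, plate-position (spatial) biases, donor-pool
variability within an experiment, and optical artifacts other than
Gaussian localization noise and uniform detection dropout. Passing
tests therefore demonstrate the pipeline's correctness and calibration
under these idealized conditions, not instrument-level performance.

## Tracking

Detection (for image input) is difference-of-Gaussians band-pass,
local maxima above threshold, and intensity-weighted centroid
refinement in a ±2σ window. Linking is Crocker–Grier-family: per
consecutive frame pair, assignments minimize the total squared
displacement over the feasible bipartite graph (links longer than
`max_displacement` forbidden; an unlinked track or detection costs
`max_displacement²`), solved exactly per connected component with
scipy's Jonker–Volgenant solver; mutually-isolated candidate pairs
short-circuit the solver. A track missing up to `memory` (default 1)
consecutive frames stays eligible within the same radius. This is
deterministic for a given input order; cost ties (measure zero for
continuous coordinates) resolve by the solver's deterministic choice.
`max_displacement` defaults to twice the fastest expected per-frame
displacement. Tracks shorter than `min_track_length` (default 5) are
discarded as quality control.

Kinematics over memory gaps: elapsed time uses the true frame span;
path length uses the straight segment across the gap — an unbiased
time base and a conservative (never inflating) path length.

## Classification and summaries

IM if VCL < 15 µm/s; else PM if VSL ≥ 25 µm/s; else NPM. The
thresholds are explicit configuration: the published screen's exact
rule lives in its platform companion and is not public, so these
WHO/CASA-convention-like values are an assumption. Under the default
motion parameters the three classes are nearly separable (confusion
< 0.3%). The per-well statistic averages the two field medians;
pooling all tracks before one median is available as
`summarize_well(..., pool_fields=True)` since the published wording
supports either reading. A well with zero tracks in both fields is
flagged invalid and excluded, never scored as zero.

## Normalization, hits, reporting

The DMSO reference is the median of the control wells' per-well
values (not pooled tracks — the pooled alternative follows from the
pooling option above). Hit rates are reported to one decimal with
half-up rounding, matching screening-table precision. A combined
"total" hit rate is ambiguous between pooling and averaging, so
`library_totals` reports both the pooled rate and the unweighted mean
of per-library rates, labelled; with the published seven-library
counts these are 0.6% and 1.2% respectively, and the per-library hit
counts sum to 105.

## Dose–response fitting

`fit_4pl` minimizes least squares of `y(x) = d + (a−d)/(1+(EC50/x)^hill)`
with a trust-region solver, analytic Jacobian, and eight deterministic
starts (two log-spaced midpoint guesses × hill ∈ {±0.5, ±2}); the
best residual sum of squares wins. Bounds for 8-point designs:
d ∈ [50, 150] %, a ∈ [50, 300] %, EC50 within [lowest dose/10, highest
dose×10], |hill| ≤ 10. The model is invariant under swapping plateaus
and negating the slope, so fits are canonicalized to hill > 0, making
`lower_asymptote` the zero-dose plateau and `upper_asymptote` the
saturating plateau (the maximal effect for an enhancer). The fitted
curve passes through (EC50, (a+d)/2) by construction. Exactly
constant responses short-circuit; fitted plateaus closer than 0.5
percentage points are flagged degenerate (EC50 unidentifiable) rather
than raising. ECx is reported as the fitted midpoint paired with the
maximal effect; the absolute-effect reading (concentration reaching a
stated % of control) is the separate, explicit `ec_absolute`.
Suspect high-dose points are a flagging concern for real data; this
package fits all supplied points and leaves outlier exclusion to the
caller. Confirmation requires every experiment's fit to converge with
an upper plateau ≥ 100 + `min_effect` (default 20) % of control.

## Chemical space

Fingerprints hash iteratively grown atom neighborhoods (initial
invariants: element, charge, aromaticity, hydrogen count, degree;
then sorted bond-order/neighbor-id multisets) with a platform-stable
CRC32 mix, folded to 2048 bits at radius 2. Bit positions are NOT
RDKit-compatible; `rdkit_fingerprint` is the adapter when toolkit
parity matters. SMILES parsing is RDKit's; aromatic flags are trusted
as parsed. Similarity is Tanimoto; groups are single-linkage
components at threshold 0.55 (a common medicinal-chemistry
heuristic). 2-D embedding is delegated (PCA fallback, UMAP when
installed) and provenance-stamped; the published embedding's
hyperparameters are unstated, so no layout reproduction is claimed.

## Numerical and scale choices

Desk-scale problem sizes throughout are the package's own choice so
that the full test suite and the acceptance script each run in
minutes on one CPU: 500 cells/field for plate runs, 10,000 tracks for
distributional checks, 500 Monte-Carlo repeats for EC50-recovery and
100 for confirmation-rate estimates. All randomness flows through
explicit integer seeds via `numpy.random.SeedSequence`; per-well
streams derive from (plate seed, well index, field index), so any
well regenerates bit-identically in isolation.

## Known limitations

- Compound-specific published results (ECx tables, target-class
  composition) require the original raw screen data and are not
  reproducible here; the package reproduces the *procedures* and
  validates them on synthetic ground truth.
- The linker is per-frame-pair optimal, not globally optimal over
  whole trajectories; dense fields produce occasional identity swaps,
  which bias the well median by ~2% at default densities (equally in
  control and compound wells, so normalized values are insensitive).
- No spatial plate-effect correction is implemented (none is used by
  the screen this mirrors); systematic row/column gradients would
  pass through normalization.
- The IM class's measured VCL is localization noise, not biology; at
  very high frame rates the noise floor approaches the IM threshold.
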