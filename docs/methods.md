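# Methods

This note documents the models, algorithms and design choices behind
`pocketscreen`, module by module, including the parameters that matter and
the known limitations of each stage.

## Structure model

Structures are flat ordered lists of atom records parsed from fixed-width
PDB via gemmi. Only the first model of a multi-model file is used.
Alternate locations collapse to the highest-occupancy conformer (ties:
first encountered). HETATM groups and waters are excluded by default;
waters are always excluded. Coordinates stay in the file's frame — nothing
re-centers at parse time, so detected pocket geometry is directly
comparable with the input coordinates.

The polar-residue set used for pocket composition is fixed and documented:
the charged residues (ARG, LYS, HIS, ASP, GLU), the polar-uncharged ones
(SER, THR, ASN, GLN), and TYR, CYS, TRP, whose side chains carry
hydrogen-bonding heteroatoms — 12 of the 20 standard residues. "Polar" has
no single canonical definition; this set is a package decision, and
`residue_is_polar` is the single point of configuration. Van der Waals
radii are the Bondi values (C 1.70, N 1.55, O 1.52, S 1.80 A, ...);
unknown elements warn and default to 1.70 A.

## Pocket detection

Detection is a two-probe difference method on a voxel grid. A voxel is
protein iff its center lies within the van der Waals radius of any atom.
For a probe of radius r, accessibility is computed exactly with Euclidean
distance transforms: probe centers are solvent voxels at distance >= r
from protein; reachable centers are those 26-connected to the box
boundary; accessible(r) is every solvent voxel within r of a reachable
center. This equals the morphological opening of solvent space by a ball
of radius r, restricted to the bulk-connected component, and costs the
same for any probe radius.

Pocket space is accessible(small) \ accessible(large), with defaults of
1.4 A (water) and 4.0 A (envelope). Cavities sealed away from bulk solvent
are retained (they are small-probe spaces with no path to the boundary)
and report zero mouths. Components are 26-connected; mouths are 26-connected
patches of pocket voxels that are face-adjacent (6-adjacency) to
envelope-accessible space. Lining atoms are the nearest atoms of protein
voxels face-adjacent to the pocket. Pockets sort by volume descending with
the lowest flattened voxel index as the tie-break, so output order is
reproducible bit for bit at a fixed spacing.

Measurements:

* **volume** = voxel count x spacing^3.
* **area** = pocket/protein boundary face count x spacing^2 x 2/3. Raw
  face counting overestimates a smooth, isotropically oriented surface by
  exactly E[|n_x|+|n_y|+|n_z|] = 3/2, so 2/3 is the unbiased correction;
  it undercounts axis-aligned planar walls by the same factor. The
  constant is an argument (`area_correction`) for callers who prefer a
  different convention.

Filtering applies the druggability criteria: pockets below the minimum
wall area (default 500 A^2) or with fewer than the minimum polar lining
residues (default 2) are excluded outright; pockets with other than one
mouth survive but are flagged `multi_mouth_deprioritized` and ranked after
all single-mouth pockets, reflecting that drug-binding pockets are almost
always single-mouthed without discarding the rest.

This grid method is deliberately not an alpha-shape reconstruction: it is
self-contained and testable against analytic solids. Validation is by
analytic-shape oracles (below), not by parity with any particular
alpha-shape tool, and the 500 A^2 area criterion refers to this grid
boundary area.

## The analytic cavity fixture

The synthetic slab fixture provides the geometry oracle. A cubic lattice
(0.6 A pitch) of carbon pseudo-atoms forms a solid slab; a spherical
cavity of radius r (3-10 A) is carved below the top face, connected to the
surface by a cylindrical mouth channel of radius 2.4 A — wide enough for
the 1.4 A water probe, too narrow for the 4.0 A envelope probe — or fully
sealed. Atoms are kept when their center clears the cavity solid by at
least r_vdw - pitch/4, which centers the bumpy atomic wall on the analytic
surface instead of biasing it inward or outward.

A geometric point worth recording: an *open bowl* (hemisphere carved flush
into a flat face) is not a pocket under any probe-difference definition
with these probes. For a bowl of radius 5 A, envelope-probe centers with
clearance >= 4 A exist all the way down to the bowl center (for an
interior point x, the center x/|x| is within |x| - 1 <= 4 of it), so the
entire bowl is envelope-accessible and the pocket volume is zero. A
meaningful volume oracle therefore requires a constricted mouth, which is
exactly what real binding pockets have; the buried-sphere-with-channel
design makes the analytic volume (4/3) pi r^3 + pi a^2 L exact up to two
small continuum corrections (the envelope probe's spherical-cap intrusion
at the channel top, and the water probe's wedge exclusion at the
channel/sphere junction), together about 1-2% for r = 5.

Measured behaviour for the r = 5 open fixture: volume error -4.3% at
0.5 A spacing and -3.2% at 0.25 A (monotone toward the analytic value);
the sealed-sphere wall area reproduces 4 pi r^2 within 13% under the 2/3
face correction. What these tests do **not** show: performance on real
protein surfaces with mixed radii, partial occupancies, rough lining, and
mouths near the probe-size boundary, where pocket/bulk partitioning is
genuinely ambiguous.

## Shape signatures and their comparison

A pocket's shape signature is the multiset of all n(n-1)/2 pairwise
distances between lining atoms — invariant to rigid motion, sensitive to
uniform scaling, cheap to compare. All pairs are used (no subsampling).
Two signatures are compared with the exact two-sample Kolmogorov–Smirnov
statistic on the raw multisets; the 0.5 A histograms are presentation
artifacts only. The p-value uses the asymptotic Kolmogorov distribution at
effective sample size n1 n2 / (n1 + n2) and is approximate below
n_eff ~ 35 (distances within a signature are also not independent, so p
is a ranking score, not a calibrated tail probability). Library search
ranks by ascending D, ties broken by descending p then lexicographic id;
hits with D below 0.25 are flagged as similarity candidates — that
threshold is a package default for flagging, not a measured constant.

## Surface alignment and composite scoring

* **Correspondence.** When no pairing is supplied, lining atoms are
  matched greedily within chemical classes (N, O, S, everything-else-C)
  by smallest centroid-centered distance, deterministically. Exactness
  tests use explicit user-supplied correspondences.
* **Superposition** is the Kabsch algorithm: SVD of the paired covariance
  with the reflection corrected to determinant +1; cRMSD is the RMS paired
  residual after the optimal motion. Collinear point sets are rejected by
  name (the rotation about the common axis is unidentifiable).
* **Orientation agreement (oRMSD).** Per residue, the unit vector from CA
  to the side-chain heavy-atom centroid; glycine (no side chain) is
  skipped and reported, as are residues missing CA or side-chain atoms.
  oRMSD = sqrt(mean |R u - v|^2), range [0, 2].
* **Significance.** The empirical p-value scores the observed alignment
  against n_null random alignments: uniform random rotations (quaternion
  sampling, seeded) of one pocket about its centroid, each with the
  correspondence re-derived and scored identically to the observed
  alignment (default score: cRMSD; swappable via `score_fn`).
  p = (1 + #worse-or-equal) / (1 + n_null), so the best attainable p is
  1/(1 + n_null). Note the null is about the *correspondence*, not the
  shape: a rotation that the greedy matcher can undo scores identically
  to the observed alignment, which is the intended meaning of "random
  alignments".
* **Volume overlap (gSVOT)** maps one pocket's voxel centers through the
  alignment, re-rasterizes them to the other's grid by nearest voxel, and
  takes intersection-over-union. Rasterization makes it asymmetric at the
  0.05 level at 0.5 A spacing.
* **Composite score** = geometric mean of (1 - D), (1 - p), and gSVOT,
  each clamped to [1e-6, 1]. The geometric mean makes the composite
  monotone in each similarity component and lets any single near-zero
  component veto the comparison; the combiner is isolated in one function
  and trivially swappable.

## Compound triage

The drug-likeness window keeps compounds with molecular weight in
[160, 480] g/mol (inclusive), TPSA < 140 A^2, HBD < 5 and HBA < 10
(strict), with per-record rejection reasons; all four thresholds are
configurable. Property computation from SMILES is out of scope — the
table is the interface.

The funnel treats stage scores as relative: dense ranks only (best = 1,
ties share a rank), with lexicographic compound id as the deterministic
tie-break inside a rank. Stage i keeps its top keep_count, or
ceil(keep_fraction x scored survivors), from the survivors of stage i-1.
The first stage may be several method tables run in tandem; survivors are
the union of the per-method cuts. Compounds missing a score in a later
stage are dropped with a logged reason rather than imputed — rescoring
stages operate on poses they actually scored. The final ranking is the
last stage's rank order truncated to final_k (default 100). Default keep
fractions in the fixture generator (0.25, then 0.5) are placeholders for
testing the mechanics, not empirical claims.

## Screening analytics

Percent of control is 100 x mean treated colonies / mean control
colonies, per cell line and day. The efficacy ratio divides a cancer
line's percent-of-control by the bone-marrow percent-of-control at the
same concentration; ratios below 0.5 are classed active and at least
partially selective. Relative activity is the percent of tested cell
lines active for a compound; site summaries report the percent of a
site's compounds with at least one active line, the pooled mean ± SEM
over *all* sub-cutoff ratios of the site's active compounds (sample SEM,
n-1; a single pooled value reports SEM 0.0), and the min–max of relative
activity. Missing table entries ("-") are first-class: excluded from
numerators and denominators, never zero. Marrow toxicity flags count
compounds whose 8-day inhibition (100 - percent of control) strictly
exceeds 10% and 30%.

Printed-table conventions: ratios round to 2 decimals and percentages to
integers with half-up rounding (62.5 -> 63), while classification always
uses unrounded values. The bundled reference screening dataset (38
compounds across 8 protein sites, 9 cancer lines plus CD34+ marrow)
reproduces its published summary statistics exactly under these rules,
with one exception: the source table's footer prints 73% relative
activity for FolC1-020, but its own printed column (5 active of 7 tested
lines) computes to 71%; the package reports the recomputed value, and the
FolC1 activity range computes as 43–71 accordingly. Published SEMs were
evidently computed from unrounded ratios, so the package asserts pooled
means (which survive 2-decimal rounding) rather than SEMs.

## Dose–response fitting

The four-parameter logistic model is
y = bottom + (top - bottom) / (1 + 10^((log10 IC50 - log10 x) * hill)),
fitted by Levenberg–Marquardt least squares on log-transformed doses.
Zero-dose controls are the normalization denominator and are excluded
from the fitted points (log 0 undefined); at least 4 distinct positive
dose levels are required. Initialization: bottom/top from the response
extrema, log IC50 from the dose nearest the half-response, Hill sign from
the response trend. Flat responses and non-convergence raise explicit
errors carrying diagnostics — never a silent failure. If the optimizer
returns bottom > top, the asymptotes are swapped with the Hill sign
flipped (the parameterization is exchangeable).

The colony-count generator places counts on a known 4PL curve with
multiplicative log-normal noise of a given CV (mean exactly 1), rounded
to integers. Two dose grids are bundled: the nine-point screening grid
(0.0061–40 uM) and the five-point IC50-assay grid (0.001–10 uM). The
Monte-Carlo recovery study uses the IC50-assay design — grid bracketing
the true 12 nM value, 3 replicates per dose — because that is the
protocol under which such an IC50 is measurable: on the screening grid a
12 nM IC50 sits below the lowest dose, the upper plateau is unsampled
(max response ~66%), and the unconstrained 4PL top parameter becomes
unidentified, inflating the dispersion of recovered IC50s several-fold.
Under the assay design the median recovered IC50 over 200 replicates at
10% CV is within ~2% of truth. Integer colony counts add a quantization
floor of roughly 3% median IC50 error at 200 control colonies; tests of
the zero-noise limit use larger plates to isolate the noise effect.

## Determinism and numerical conventions

Every stochastic operation takes an explicit seed; fixture families
derive per-generator child seeds from one master seed by a stable sha256
hash, so a fixture set regenerates byte-identically. Random rotations use
uniform quaternion sampling. Grid outputs are deterministic at fixed
spacing, including pocket ordering and the funnel's tie policy (input
order never affects output). Exact ECDF comparisons are float-exact: a
rigid motion can perturb pairwise distances at the 1e-15 level and flip
single <= comparisons, so "invariance" holds to one ECDF step, not to
machine epsilon.

## Problem sizes

Default validation sizes: the r = 5 A cavity fixture (~19k pseudo-atoms)
gridded at 0.5 and 0.25 A; 100 random multiset pairs (n <= 200) for the
KS oracle; 1,000 random correspondence sets against a 300-rotation probe
oracle for superposition; 200 replicates for IC50 recovery; 150 compounds
x 3 stages for the funnel oracle. Each suite completes in seconds to tens
of seconds on one CPU.

## Known limitations

* The detector approximates, not reproduces, alpha-shape pocket
  boundaries; areas depend on the face-count convention.
* KS p-values are asymptotic and treat within-signature distances as
  independent; use D for ranking.
* The greedy correspondence is a heuristic; it can lock into a suboptimal
  matching for highly symmetric pockets, which inflates cRMSD (never
  deflates it below the optimum for the chosen pairing).
* The composite score's geometric-mean combiner is a documented choice,
  not an identified model.
* Funnel keep schedules are configuration, with no claim about any
  particular historical screen.
* The analytics assume the marrow line is the selectivity denominator;
  other normal-tissue baselines are not modeled.
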