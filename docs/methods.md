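# Methods

This note records the models, conventions and numerical choices behind
`mdpost`, and what the synthetic-data tests do and do not demonstrate.

## Units and indexing

Coordinates are in Å, energies in kcal/mol, times in ns, temperature in K.
Residue numbering is 1-based and taken verbatim from input files (PDB
convention); frame indices are 0-based internally and reported 1-based in
every output table. All standard deviations are sample SDs (ddof = 1); a
series of length one reports SD 0 with n = 1 so the degenerate case is
visible rather than NaN.

## Superposition and geometry observables

Optimal rigid superposition uses the Kabsch SVD construction with the
determinant correction that excludes reflections. Degenerate inputs
(< 3 atoms, or a collinear point set, detected by rank of the centered
coordinates at tolerance 1e-8) are rejected rather than silently fitted.

RMSD defaults to Cα atoms: the observable should match the metric used for
conformational clustering, and Cα-based RMSD is that metric. Backbone or
arbitrary selections are accepted wherever a `Selection` is taken.

The reference structure for RMSF, DCCM and PCA is the trajectory average
after **two** superposition iterations (fit to first frame, average, refit,
re-average) — the conventional essential-dynamics protocol. The fit absorbs
six rigid degrees of freedom, so per-residue RMSF is biased low by a factor
of roughly √(1 − 6/3N); for the chain sizes used here (N ≥ 100 in
quantitative tests) this is under 1% and the planted-noise law
RMSF = σ√3 is recovered within 5%.

The radius of gyration is mass-weighted (unit masses if none are given);
RMSF is unweighted and per-Cα. Segment statistics use half-open intervals
[b_i, b_{i+1}) over strictly increasing interior breakpoints.

## Hydrogen bonds, contacts, descriptors

The geometric H-bond criterion is donor–acceptor heavy-atom distance
≤ 3.5 Å and D–H···A angle ≥ 135°. Published occupancy figures in this
problem domain rarely state their criteria, and occupancies are sensitive
to both cutoffs, so both are configuration keys rather than constants.
Hydrogens are paired with donors by covalent distance (≤ 1.25 Å within the
same residue); a donor with no attached hydrogen is an error, not a silent
skip. Occupancy of a donor–acceptor pair is the fraction of frames in which
that pair passes the criterion.

Contact residues use heavy atoms only, at a 4.0 Å cutoff, via a k-d tree;
results are reported as (chain, residue index, residue name).

Ligand descriptors act on a minimal heavy-atom connection table with
implicit hydrogens. Conventions:

* molecular weight: standard atomic weights, reported to 2 decimals;
* rotatable bonds: acyclic single bonds whose endpoints both have
  heavy-atom degree > 1. Ring membership is cycle membership (a bond is in
  a ring iff it is not a graph bridge). Hydroxyl C–O bonds are therefore
  not rotatable (terminal oxygen) — this convention gives the canonical
  count of 2 for the bundled trihydroxy-stilbene ligand and matches the
  common cheminformatics default on the molecules tested;
* H-bond capacity: one donor per O–H/N–H, one acceptor per O/N; the
  theoretical maximum simultaneous H-bond count is their sum;
* the rule-of-five check evaluates the three graph-computable rules
  (MW ≤ 500, donors ≤ 5, acceptors ≤ 10). No logP estimator is included;
  the result lists exactly which rules the pass flag covers.

The descriptor suite is cross-checked in the tests against an independent
cheminformatics toolkit on a ten-molecule set; the toolkit is never a
runtime dependency.

## Conformational clustering

Frames are clustered in the flattened Cα coordinate space after the
average-structure fit, so Euclidean distance approximates pairwise Cα RMSD
(times √N) while keeping centroids well defined — the same convention as
the widely used trajectory clustering tools. Defaults follow the standard
protocol: k scanned over 2..10, at most 1000 Lloyd iterations, sieve 10
(k-means runs on every 10th frame; remaining frames join the nearest
centroid; validity indices are computed on the full assignment).

Initialization is seeded k-means++ with 50 restarts. Uniform random-point
seeding was considered and rejected: a state occupying a fraction of a
percent of the trajectory contributes only one or two sieved frames, which
uniform seeding essentially never selects, and Lloyd iterations cannot
subsequently discover an unseeded distant micro-cluster. D²-weighted
seeding finds it reliably; with 50 restarts the failure probability is
negligible at the default sizes.

Validity indices are implemented directly from their definitions
(Davies–Bouldin with s_i = mean member–centroid distance; pseudo-F =
(SSR/(k−1))/(SSE/(n−k)), identical to Calinski–Harabasz; SSR/SST) and are
cross-checked against scikit-learn where it implements them. Degenerate
geometry yields +inf (coincident centroids, zero SSE) rather than an
exception, so a scan can continue past a pathological k.

k selection: k_best minimizes DBI; among k values within 5% relative DBI
of the minimum, the highest pseudo-F wins. Both the choice and the full
per-k table are emitted so any other combination rule can be applied. The
scan is flagged **ambiguous** when several k tie under that rule or when
the DBI minimum is a shallow valley — above 70% of the scan's median DBI.
The 70% figure separates the two regimes we generate: a genuine multi-state
trajectory produces a pronounced valley at the true k (minimum well under
half the median), while a single featureless basin produces a gently
drifting curve whose minimum is near the median.

Representative frames minimize Euclidean distance to the centroid, ties
broken toward the lower frame index.

## DCCM and PCA

Both operate on Cα displacement vectors about the iterated average after
fitting (a `fit=False` path exists for inputs known to carry no rigid-body
motion, and is what the brute-force oracle tests use). DCCM entries are the
displacement-vector dot-product covariances normalized by the per-atom
fluctuation magnitudes; entries are clipped to [−1, 1] against round-off,
the diagonal is exactly 1, and a zero-fluctuation atom raises an error
naming the residue. Covariances use the 1/F (time-average) normalization.

PCA diagonalizes the full 3N × 3N covariance with a symmetric
eigendecomposition; all 3N eigenvectors are kept (789 for 263 residues),
eigenvalues are sorted descending and clipped at zero, explained fractions
are eigenvalues over their sum, and projections are the centered flattened
coordinates on the eigenvectors. No mass weighting: all selected atoms are
Cα carbons, so weighting would rescale uniformly.

## MM/GBSA bookkeeping

The module consumes per-frame component deltas produced under the
single-trajectory convention; ΔE_internal ≡ 0 is permitted and flagged (the
internal terms cancel exactly when complex, receptor and ligand frames come
from one trajectory). It deliberately contains no GB/SA solver and no
entropy estimator — those are upstream, cluster-scale computations; this
module is the aggregation arithmetic.

Block protocol: the series is split into `n_blocks` equal contiguous
blocks (default 20, i.e. 50 ns each for a 1 μs run); within each block
`snapshots_per_block` values (default 100) are taken at a regular stride;
the reported value is mean ± SD of the block means. Entropy estimates
arrive as per-snapshot TΔS values grouped in blocks (default 5 × 20) and
aggregate the same way; blocks must be equal-sized.

ΔG_bind = ΔH − TΔS with TΔS stored directly in kcal/mol, so an
unfavorable entropy term (negative TΔS) raises ΔG_bind. Default
temperature 310 K (physiological, the simulation temperature).

Per-residue decomposition averages each residue's contribution over frames
and flags key residues at ΔG_res **≤** −1.5 kcal/mol. The boundary is
included deliberately: a residue exactly at the threshold is as favorable
as the rule demands. The residue set must be identical in every frame.

## Elevated-plus-maze scoring

AI = 1 − ½(T_op/T + N_op/N) ∈ [0, 1]; higher is more anxious. An animal
with N = 0 has an undefined index and raises an error rather than
returning a sentinel. Correlations default to Pearson's r (the convention
for the published correlation figures this mirrors; they do not state the
estimator), with Spearman available by configuration. ANOVA and post-hoc
testing are intentionally out of scope — the group tables are emitted in a
form any statistics package consumes.

## Synthetic-data generators

The generators are first-class, tested code: every planted parameter must
be recoverable by the corresponding analysis operation, and the test suite
enforces this.

* **Trajectory**: each frame is its dwell segment's reference conformation
  plus isotropic per-residue Gaussian noise, optionally wrapped in a random
  rigid transform per frame (to exercise the fitting path). The default
  emulates the studied receptor's shape: 263 residues, 5000 frames, three
  states with transitions at 0.4% and 30% of the run (the analogue of
  changes at ~4 ns and ~300 ns in a 1 μs trajectory), baseline σ = 0.4 Å
  with two 3σ mobile windows around the 131 and 230 positions. The late
  conformational change displaces a 20-residue loop by 8 Å; the initial
  state sits 20 Å out along a different direction, reflecting the
  larger-amplitude motion at the start of such runs. The initial state's
  extra separation matters: with a 0.4%-population state, merging it into a
  neighbor barely inflates that cluster's scatter, so only a clearly more
  distant third state produces the pronounced DBI valley at k = 3 that real
  multi-state data shows. Reference chains are smooth compact pseudo-Cα
  paths (3.8 Å steps, correlated directions) rescaled to R_g = 17.8 Å.
* **H-bond distance series**: concatenated Gaussian regimes truncated at
  zero; the default is an unbonded ~6 Å regime followed by a bonded
  1.77 ± 0.12 Å regime occupying 59% of frames.
* **Energy tables**: independent Gaussian per-frame components with means
  summing to ΔH = −23.6 kcal/mol; per-residue contributions split each
  frame's interaction energy in proportion to the planted residue means, so
  additivity holds exactly frame-wise. Planted key residues: −2.2, −1.7,
  −1.6 kcal/mol, one near-miss at −1.2, and a background of small
  contributors.
* **EPM cohorts**: four groups (vehicle, effective dose, stressed,
  stressed + treated) with means chosen to give AI ≈ 0.8 / 0.6 / 0.93 /
  0.67 over a 600 s session, clipped to the record invariants; a synthetic
  enzyme-activity covariate is constructed with a planted correlation
  (default ρ = 0.9) against the realized AI values.

What passing these tests shows — and does not. The generators are Gaussian
state-noise models: no solvent, no side chains, no heavy-tailed or
autocorrelated fluctuations, no force-field physics. Recovery therefore
demonstrates that the analysis arithmetic is correct and well-conditioned
at realistic sizes, not that the pipeline would draw correct scientific
conclusions from any particular real trajectory. Frame-level energy noise
is likewise iid, so block SDs here are smaller than those of correlated
real data.

## Problem sizes

Quantitative defaults were chosen as desk-scale analogues of the study
protocol: 5000-frame trajectories stand in for 50 000-frame production
runs (same block structure: 20 blocks, stride-sampled snapshots), and the
smaller fixtures in the unit tests (40–100 residues, 400–600 frames) keep
the full suite under a minute while remaining above the sizes where the
estimators' small-sample biases matter (documented above for RMSF).

## Known limitations

* The multi-model PDB reader handles coordinates, names, chains and
  1-based residue indices; altlocs, insertion codes and SEGIDs are ignored.
  Binary trajectory formats are out of scope by design.
* The H-bond detector infers D–H attachment geometrically; it does not read
  connectivity records.
* No logP estimation, no aromatic-geometry (ring-plane angle) scoring.
* `pseudo_f`/`davies_bouldin` return +inf on degenerate partitions instead
  of raising; callers scanning k should filter non-finite rows (select_k
  does).
* The anxiety index treats open-arm time and entry fractions with equal
  weight; no alternative weighting is offered.
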