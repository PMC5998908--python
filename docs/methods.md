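# Methods

## Model and procedure

The package treats complex detection as flow-based graph clustering plus a
biologically informed post-process. The assumptions are the classic ones of
this problem family: (1) protein complexes appear as locally dense regions
of the PPI network, so a random walk started inside a complex tends to stay
there; (2) subunits of one complex are co-expressed — their mRNA time
courses rise and fall together across the metabolic cycle — so complex
membership leaves a signal in expression data that pure topology misses;
(3) both signals are noisy, hence candidates are first generated cheaply
(MCL) and then filtered and repaired using both signal families.

### Edge weighting

Raw interaction edges are unweighted and noisy. The Jaccard coefficient of
the endpoint neighbourhoods rewards edges embedded in shared neighbourhood
structure and damps spurious one-off interactions. The diagonal entry of a
vertex is the maximum off-diagonal entry of its row: the printed index
form of the source formula is internally inconsistent (`max_{k≠j} A(i,k)`
on a diagonal case `v_i = v_j`), and the row-maximum reading is the only
one that type-checks; it gives each vertex a self-loop proportional to its
strongest incident similarity, the usual device that stops flow from
oscillating on bipartite-like structure.

Two degenerate cases need decisions the formulas do not make:

* **Zero-Jaccard edges.** A leaf edge has no shared neighbour, weight 0,
  and would disconnect the walk from the leaf. Edge weights are therefore
  floored at `floor` (default 0.01, applied to true edges only;
  `floor = 0` reproduces the literal formula).
* **Isolated vertices.** A degree-0 vertex has a zero column; it gets a
  unit diagonal at normalisation time, forms a singleton attractor, and is
  discarded by the minimum-size rule downstream.

### MCL

Expand is the matrix square; Inflate is entrywise power r followed by
column renormalisation (default r = 2); Prune zeroes, per column, entries
strictly below `thd(j) = avg(j) − w · var(j)` where `avg` and `var` are the
mean and *population* variance over the column's support (default w = 1),
then renormalises. The population form of the variance is used exactly as
printed, not the sample form. `thd(j)` may be ≤ 0 for high-variance
columns; nothing is pruned there, no clamping. The column maximum is always
≥ avg ≥ thd, so pruning can never empty a column (asserted).

Convergence is not further specified by the source, so the loop stops when
the max-norm change of one full [expand → inflate → prune] iteration falls
below `tol` (default 1e-6, standard MCL practice) or after `max_iter`
(default 100) iterations with a logged warning. Each iteration consumes
the pruned, renormalised matrix of the previous one — the only
self-consistent reading of "prune at the end of each iteration".

At convergence most columns concentrate on one attractor row, but exact
single-support columns are not guaranteed at an iteration cap, so
extraction takes each column's argmax (ties to the lowest vertex index,
for determinism) and union-finds vertices with their attractors. No step
in this module uses randomness; identical inputs give identical partitions.

### Co-expression

Time courses are max-normalised per protein (`T′_i(l) = T_i(l)/max_l T_i`),
making the score scale-free in expression magnitude. The pairwise score
`E_co = Σ_l ln[(T′_i+T′_j)/|T′_i−T′_j|]` is +∞ as printed whenever two
values coincide; the absolute difference is clamped below at δ = 1e-3
(configurable), so identical profiles score very high (ln 2000 per
interval) but finite, preserving the intended ranking. Intervals where
both values are ≈ 0 (sum < δ) are skipped: ln(0/0) is undefined and such
points carry no co-expression signal. All-zero rows therefore contribute
E_co = 0 everywhere. Proteins present in the network but missing from the
expression file score E_co = 0 and Co = 0 against everyone and are
excluded from E_co(avg) — real expression compendia cover "most" but not
all network proteins, and absence of evidence is scored neutral-low.

E_co(avg), the reference point of the binary Co indicator, is by default
the mean over *all* unordered protein pairs with data (the literal reading
of "all pairs of proteins in the network"); an `edges` scope restricted to
interacting pairs is available as a documented cheaper alternative on
large networks.

### Features

Two vertices are "n-connected" when their shortest-path distance in the
*whole network* is between 1 and n (`at_most`, the default). The source
text can also be read as exactly-n; the cumulative reading is the default
because a density feature meant to measure "intensive degree" with bounds
like 0.18/0.06 only makes sense when direct edges count, and an `exact`
mode is kept for the other reading. PathNum always counts shortest paths
of length exactly n (a count of paths *at* the shortest distance is the
only well-defined count). All |C|² denominators are kept as printed while
diagonal terms contribute 0.

Inside the seven-feature vector, n is fixed to 2: the weight vector has
seven entries, so one n must be chosen, and 2 is the first the source
names. Features enter the logistic score raw (no standardisation), because
the shipped weights were fitted on raw features.

### Filtering and modification

Triage computes Vector(C) = (Den(C,2), E_co(C), CoRatio(C)) against
(upper, lower) bounds (0.18, 0.06), (80, 50), (0.75, 0.20): any feature
below its lower bound → discard; all at/above their upper bounds →
reserve; otherwise → modify. Classification happens once, before
modification. Complexes with fewer than 3 proteins are dropped outright,
mirroring the ≥ 3 convention of curated complex catalogues.

Modification is an iterated sweep (default ≤ 10 passes): score every
member v by P(v, C∖{v}) and delete the single worst if P < 0.5 (the
logistic decision boundary); then score every external neighbour by
P(v, C) and add the single best if P > 0.8. The strict 0.8 add threshold
is the default because permissive addition is empirically far less precise
than strict addition; both knobs are exposed. One change per sweep keeps
the procedure order-independent and deterministic (lowest/highest scorer
first). A complex that shrinks below the minimum size is dropped. With
add threshold 1.0 and delete threshold 0.0 the procedure is the identity.

The original filter/modify procedures are published only as pseudocode
images unavailable in text form; the classify rule and sweep order here
are the reconstruction that reproduces the described
reserve/discard/modify semantics deterministically.

`generate_training_samples` grows random connected complexes (size uniform
in [3, 10]) by repeated random neighbour addition and labels each
candidate edit positive iff it strictly increases the complex's best
overlap score O against the benchmark — the source never defines "better",
and best-overlap improvement is this package's documented choice.
`fit_weights` is an intercept-free, penalty-free logistic regression on
the seven raw features; the shipped default weights
(0.01, 0.02, 0.01, 0.24, 0.36, 0.03, 0.33) are used when no fitting is
requested.

### Evaluation

Overlap matching uses O(C_p,C_b) = |C_p∩C_b|²/(|C_p|·|C_b|) with ω = 0.2
and the existential match definition exactly as printed (a prediction may
match several benchmark complexes). Sn/PPV/Acc are computed from the full
intersection matrix T; predictions with zero overlap against every
benchmark complex contribute nothing to either side of PPV; an all-zero T
defines PPV = 0 with a logged warning. The benchmark is used unfiltered by
default, with an optional ≥ 3-member restriction. Benchmark proteins
absent from the network are retained (set intersections need no graph).

## Synthetic data: what it emulates, what it does not

`SyntheticSpec` plants `n_complexes = 8` complexes of 4–10 proteins as
Erdős–Rényi blocks at `p_in = 0.85` over a background of 60 proteins, all
remaining pairs wired at `p_out = 0.01`. Expression gives each complex one
latent course `1 + sin(2π·3·l/36 + φ)` — three full periods over 36
intervals, echoing the periodic structure of metabolic-cycle expression
data — with a random phase per complex; members emit amplitude-scaled
copies (amplitude uniform in [0.5, 1.5]) plus Gaussian noise
(std 0.1), background proteins emit independent uniform noise on the same
value range, and everything is clipped at 0 to keep expression
non-negative. Seeded runs are bit-reproducible; the graph and expression
use separate child streams of one seed.

This reproduces the two signals the method exploits — dense blocks and
shared periodic expression — at desk scale (~112 proteins). It does *not*
reproduce the degree distribution, size or noise structure of real
interaction databases (hubs, heavy-tailed degrees, correlated false
positives), overlapping/nested complexes, or expression missingness.
Passing tests therefore demonstrate correctness of the machinery and
recoverability under the stated conditions, not performance on real yeast
networks, whose published numbers depend on the exact external datasets.

## Numerical choices

* Matrices are scipy CSC throughout; densification only in tests on tiny
  graphs. Column-stochasticity is asserted after every MCL step at 1e-7.
* Prune keeps entries with value ≥ thd (strict `<` removes); a
  single-support column is never altered.
* δ = 1e-3 in E_co; E_co cache keyed on unordered pairs.
* Argmax ties at extraction and equal logistic scores during sweeps break
  toward the lexicographically/index-smallest vertex.
* Vertex order everywhere is first appearance in the input file.

## Problem sizes used in tests and the acceptance script

The test-suite and acceptance runs use the 112-protein synthetic benchmark
above, random graphs of ≤ 30 vertices for oracle-equivalence checks (200
graphs), and the printed evaluation counts of the reference tables for the
metric identities. These sizes were chosen as the smallest at which every
claimed property is actually exercised — component separation, block
recovery, junk rejection — while keeping the whole suite fast.

## Known limitations

* E_co(avg) over all pairs is O(n²·m); on genome-scale networks use
  `scope="edges"` or precompute once and reuse the model object.
* Non-overlapping output: MCL partitions vertices, so overlapping
  complexes can only arise from modification adding shared neighbours.
* The modification sweep is greedy (one edit per pass) and can stop at a
  local fixed point.
* Weight fitting assumes both classes present and separable-ish samples;
  the shipped weights come from the original analysis, not refitted here.
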