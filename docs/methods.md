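# Methods

## Model

`trifuse` integrates one cell condition's normalized gene-by-cell expression
matrix `E` (n genes, m cells) with four condition-specific molecular
interaction networks — protein-protein (PPI), genetic (GI), co-expression
(COEX) and metabolic (MI) interactions, represented by binary symmetric
adjacency matrices `A_1..A_4` — through a joint non-negative matrix
tri-factorization with a shared gene factor:

    A_i ≈ G1 S_i G1ᵀ   (i = 1..4),      E ≈ G1 S5 G2ᵀ,

minimizing

    F = Σ_i ‖A_i − G1 S_i G1ᵀ‖_F² + ‖E − G1 S5 G2ᵀ‖_F²,   G1, G2 ≥ 0,

with `G1 ∈ R^{n×k1}`, `G2 ∈ R^{m×k2}`, `S_i ∈ R^{k1×k1}`, `S5 ∈ R^{k1×k2}`.
Because `G1` is shared by all five decompositions, the gene embedding is
informed by every data source at once; all inputs are weighted equally and no
weighting hyperparameters are exposed.

Two embedding views are used downstream. The rows of `G1` are dominated by
network structure and are used for gene clustering. The rows of
`U = G1 S5` project the gene factor into the cell-space coordinates and are
used for cross-condition comparisons, since they carry the
condition-specific expression signal.

## Solver

* **Initialization.** Deterministic, from truncated SVDs with entrywise
  absolute values: `G1` from the top-k1 left singular vectors of the
  column-wise concatenation `[A_1|A_2|A_3|A_4|E]` (so the shared factor sees
  every input), `G2` from the top-k2 right singular vectors of `E`, `S5` from
  `E`'s leading singular values, `S_i = |G1ᵀ A_i G1|`. Taking absolute values
  makes the result independent of SVD sign conventions. Inputs whose rank is
  below the requested `k` are rejected with a message advising a smaller rank.
* **Updates.** Multiplicative update rules derived from the KKT conditions,
  applied in the fixed order `G1 → G2 → S_1..S_4 → S5` per sweep, each factor
  multiplied elementwise by (negative gradient part)/(positive gradient part).
  For `G1`, which appears on both sides of the network terms, the numerator
  carries the symmetric pair `A_i G1 S_iᵀ + A_i G1 S_i`. Denominators carry an
  additive guard `ε = 1e-10`; exact zeros stay zero (standard zero-locking of
  multiplicative rules, accepted). Although only `G1, G2 ≥ 0` is required,
  this solver keeps the `S` factors non-negative too: the initialization is
  non-negative and the updates preserve sign — a deliberate restriction.
  Monotone descent of `F` holds empirically to within 1e-9 relative tolerance
  per sweep on random instances (verified in the acceptance suite); no
  square-root damping was needed.
* **Convergence.** `F` is evaluated every `check_every = 10` sweeps;
  iteration stops when the relative change between consecutive evaluations is
  at most `rel_tolerance = 1e-3`, or at `max_iterations` (default 1000). An
  exactly factorizable input drives `F` geometrically toward numerical zero,
  where the *relative* change stalls at the decay rate and never fires; the
  fit is therefore also declared converged once `F` drops below
  `zero_tolerance = 1e-7` times its initial value. For such inputs the final
  relative residual `F/‖inputs‖²` is then of order 1e-6.

## Rank selection

The latent ranks are chosen by clustering stability: for each candidate `k`,
repeated runs produce gene partitions, their agreement is summarized in a
consensus connectivity matrix `C̄` (entry = fraction of runs co-clustering a
gene pair), and the dispersion coefficient

    ρ = (1/n²) Σ_ij 4 (C̄_ij − 1/2)²

is computed; the candidate maximizing ρ wins, ties going to the smallest k.

A consensus over runs that differ only in the k-means seed is degenerate when
the factorization itself is deterministic: at ranks below the true one the
rank-k fit collapses gene blocks into a stable hierarchy, clustering that
hierarchy is equally stable, and ρ ties at 1 for every rank up to the true
one — the tie rule then always returns the smallest candidate. The scan
therefore follows consensus-NMF practice and varies the *factorization
restart*: each run perturbs the SVD initialization with multiplicative
log-normal jitter (σ = 1.5), runs a fixed 300 update sweeps, and clusters the
resulting `G1` rows with seeded k-means (10 restarts). Restarts agree when
the rank matches real structure and disagree otherwise, which is exactly
what ρ measures. With σ anywhere in roughly 1–2 the true rank of clean block
data is the unique ρ-maximizer; σ = 1.5 is the default. The gene rank `k1`
is scanned on `G1` rows; a cell rank scan would use `G2` rows analogously.

## Gene mapping matrices and movement

For one condition, the gene mapping matrix (GMM) holds all pairwise
Euclidean distances between rows of `U`, divided by `‖U‖_F`:

    GMM[i][j] = d(u_i, u_j) / ‖U‖_F.

This captures each gene's position *relative to every other gene*, invariant
to positive rescaling and to any orthogonal rotation of the embedding
coordinates — so GMMs from independently fitted conditions are directly
comparable. The movement of gene `i` between conditions `a` and `b` is

    GM_i = d(g_i, g_i'),

the Euclidean distance between gene i's GMM row in `a` and in `b`, after
restricting both GMMs to the shared genes (in sorted order). Restricting
rather than recomputing preserves each condition's own geometry and
normalization. Movement is symmetric in its arguments and zero iff the
restricted rows coincide.

## Two-step prediction

Per time point (stage): genes of the disease condition are k-means-clustered
on `G1` rows into `k1` clusters (k-means++, 10 restarts, fixed seed); each
cluster is tested for enrichment in the known disease-gene set with the
one-sided hypergeometric upper tail, `p = P(X ≥ x)` at `N = |universe|`,
`K = |annotated|`, `c = cluster size`, `x = overlap`; clusters with raw
`p ≤ 0.05` are kept (a screening step — no multiplicity correction, by
design; correction is applied only in the pathway enrichment of the final
predictions, via Benjamini-Hochberg). Stage-specific predictions are the
member genes of enriched clusters that are not themselves labelled disease
genes and are expressed (≥ 1 positive count) in the time-matched control.

Core predictions are the intersection of all stage-specific sets, ranked by
the average movement between disease and control across all time points,
largest first, ties broken lexicographically by gene identifier so outputs
are reproducible. A gene must have a movement value at every time point to
be ranked (genes expressed everywhere do); a missing value is an error
naming the gene and day, not a silent drop.

## Validation statistics

* **Rank-sum comparison** of two score distributions (movement, literature
  co-occurrence counts): one-sided Mann-Whitney U, exact null by full
  enumeration when the combined sample size is ≤ 12 with no ties, normal
  approximation with tie and continuity correction otherwise. The two paths
  agree within 0.02 absolute p at the switch point.
* **Overlap significance** of several prediction sets: empirical resampling.
  The default null draws, for each set, a uniform random subset of its
  universe of the same size, and records the multi-way intersection size
  over R = 10,000 repetitions; `p = (#{null ≥ observed} + 1)/(R + 1)`, never
  exactly zero. A draw-count variant (sample with replacement, then reduce
  to distinct members, giving slightly smaller null sets) is available via
  `with_replacement=True`.
* **Network proximity**: unweighted breadth-first shortest-path lengths from
  a target gene to each member of named gene groups; unreachable genes are
  reported separately and excluded from group means.
* **Gene-set and pathway enrichment** of predictions against a background:
  hypergeometric upper tail over the union universe, with the supported
  fraction reported; per-pathway p-values are Benjamini-Hochberg adjusted
  and the table is ranked by adjusted p (raw p, then name, as deterministic
  tie-breaks).

## Synthetic studies

The generator produces a paired control/disease study over `n_timepoints`
time points (default 4): per condition an expression matrix and four aligned
networks, plus an annotation set and ground truth. Defaults: 200 genes, 100
cells, 5 gene blocks, 5 cell blocks, noise 0.05, 20 planted disease genes,
perturbation strength 1.0, within/between edge probability 0.30/0.02, half
of the planted genes annotated, decoys 5% of genes.

* **Expression.** `E = G1* S5* G2*ᵀ + |N(0, noise_sd)|` per condition, with
  block-dominant non-negative factors. Half-normal noise keeps `E`
  non-negative without clipping artifacts.
* **Networks.** Stochastic block model aligned to the gene blocks, one
  independent draw per network kind — but shared across conditions via
  common random numbers: one uniform matrix per kind is compared against
  each condition's edge-probability matrix. Control and disease networks
  therefore differ only where memberships differ, mirroring real
  condition-specific networks induced from a single database; at
  perturbation 0 the two lines' networks are identical.
* **Perturbation.** A target block is drawn; the planted disease genes are
  drawn from *other* blocks (their geometry must actually change to
  constitute ground truth) and their latent rows and network memberships are
  mixed toward the target block with weight `min(strength, 1)` — strength 1
  reassigns them fully, forming a coherent perturbed module, which is the
  structure the enrichment screen assumes disease genes have. Mean planted
  movement is non-decreasing in the strength.
* **Annotations.** The known-disease-gene set contains
  `fraction_annotated_disease` of the planted genes plus random decoy genes,
  emulating an incomplete disease catalogue: the pipeline must generalize
  from the annotated planted genes to their unannotated module partners.
* **Dropout** (genes unexpressed in a condition) is off by default and can
  be enabled to exercise the control-expression filter of the stage step.

What passing tests on this generator do and do not show: the generator
reproduces the geometric and statistical structure the method assumes
(co-clustered disease genes, coherent cross-condition geometry shifts,
block-structured networks); it does not imitate real scRNA-seq count
distributions (library size, zero inflation, overdispersion), batch
structure, or biologically scale-free network topology. Recovery on these
studies demonstrates correctness of the machinery, not expected performance
on real data.

## Problem sizes and numerical choices

Test and acceptance runs use studies of 80–200 genes and 40–100 cells with
ranks 3–7, where a full eight-condition pipeline fits in seconds; the
consensus rank scan (5 candidates × 20 restarts × 300 sweeps at n = 200)
dominates the runtime at roughly 15 s per study. Degenerate inputs are
errors, not silent results: all-zero embeddings (no relative geometry),
empty gene filters, rank-deficient inputs at the requested rank, empty
annotation sets within the universe (warning, all p = 1). The COEX builder
ranks gene pairs by |correlation| — the sign convention is a documented
choice — and breaks ties at the cutoff lexicographically.

## Known limitations

* The S factors are constrained non-negative by construction; objectives
  whose optima need mixed-sign S are out of reach of this solver.
* Multiplicative updates lock exact zeros; escape from a zero pattern set
  at initialization is impossible.
* The movement statistic compares independently fitted embeddings; it relies
  on GMM rotation/scale invariance and assumes both fits reached comparable
  optima. Severely under-converged fits inflate background movement.
* Rank selection assumes block-like cluster structure; for data with
  hierarchical or overlapping structure the dispersion curve may tie and the
  smallest-k rule is then the binding choice.
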