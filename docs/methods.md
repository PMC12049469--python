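# Methods

## Scores

All information measures use base-2 logarithms (bits) and empirical
frequencies from counts, with 0·log 0 := 0 and no smoothing. For a label
vector C over n samples and a discretized feature A with cells a₁..a_k:

* Shannon entropy H(C) = −Σ_c p(c) log₂ p(c);
* conditional entropy H(C|A) = Σ_i (|C_{A=aᵢ}|/|C|) · H(C_{A=aᵢ});
* information gain IG(C, A) = H(C) − H(C|A), identically the KL divergence
  KL(p(a,c) ‖ p(a)p(c)). Both routes are implemented and a property test
  holds them equal within 1e-9 on random contingency tables (they differ
  only in float summation order);
* classification effectiveness CE = IG/H(C) × 100%, the fraction of the
  attainable class information a subset's discretization captures.

KL(p‖q) with q(x) = 0 where p(x) > 0 is treated as an error by default
(an `allow_infinite` flag returns `inf` instead), rather than silently
producing infinities inside the search.

A note on notation: the conditional entropy above is written H(C|A)
throughout the package even though the field sometimes abbreviates it H(A)
when the conditioning context is clear; the implementation is always the
label-given-feature form.

## Discretization

**Single genes** are discretized by a one-dimensional Gaussian-mixture model
fitted by EM (scikit-learn's `GaussianMixture`, diagonal covariance,
k-means initialization from a fixed seed). Components are relabeled in
increasing order of mean, and each sample receives its maximum-posterior
component as a categorical code. The default component count is 2 — the
codes are scored against a (typically binary) label, and extra components
only fragment the contingency counts — with an optional BIC selection over
2–4. Requesting more components than distinct values is an error;
non-convergence within `max_iter` returns a flagged result with a warning.

**Gene blocks** are discretized jointly by fuzzy c-means over the
|S|-dimensional sample vectors (Euclidean distance), iterating the standard
Bezdek updates

    v_k = Σ_i u_ik^m x_i / Σ_i u_ik^m
    u_ik = 1 / Σ_j (d_ik / d_jk)^(2/(m−1))

from a seed-controlled random row-stochastic membership matrix until the
maximum membership change falls below `tol`. Defaults: fuzzifier m = 2,
tol = 1e-5, max 300 iterations. A sample coinciding exactly with a centroid
receives membership 1 there. Clusters are canonicalized by increasing
centroid norm, hard codes are taken by row-wise argmax (ties to the lowest
cluster index), and `n_init` > 1 runs several seed-derived restarts keeping
the lowest-objective solution. Gene rows are z-scored before clustering by
default so genes on different intensity scales contribute comparably; a
flag disables this. The inner loop is JIT-compiled with numba when
available, with an equivalent pure-numpy fallback.

**Cluster count for blocks.** The cell count of FCM(S) must be able to
represent every joint low/high state of the block: with only
class-many clusters, a purely synergistic pair (jointly but not marginally
informative — the object this method exists to find) is provably invisible,
because no 2-cell partition of an XOR-patterned plane separates the four
joint states. The default is therefore adaptive,
c = min(n_classes^|S|, cap), with the cap set by an occupancy rule
clamp(n/15, 2, 8): IG computed from empirical cell frequencies inflates
with arity, and under the search's max-over-thousands selection pressure an
over-fragmented noise block would otherwise outscore genuine synergy.
Measurements on the synthetic benchmark (n = 60) that motivated the cap: at
c = 8, marginal+noise quads reached IG ≈ 0.84 under selection while the
genuine XOR triple scored ≈ 0.6; at c = 4 the XOR triple (≈ 0.50) dominates
pure-noise triples (max ≈ 0.17 over 300 draws). A fixed `c` remains fully
configurable.

## Search

Stage 1 scores all M genes (EM + IG) and keeps the top K, ties broken by
ascending row index. Stage 2 takes the N best as singleton subsets, which
keep their EM-based IG as baseline (joint FCM scoring starts at |S| ≥ 2).
Stage 3 repeats for up to δ rounds: every retained subset S is extended by
every pool gene y ∉ S; the child's block is FCM-discretized and scored; the
child is accepted iff (IG_new − IG_S)/IG_S ≥ ψ (or IG_new > 0 when
IG_S = 0). An absolute-ΔIG mode is available behind `psi_absolute`.
Duplicate children reached from different parents are canonicalized by
sorted gene indices and evaluated once, with acceptance judged against the
strongest proposing parent — so an accepted child clears the ψ bar for
*every* parent it extends. FCM scores are memoized per gene set within a
run. A `beam_cap` (default 200) retains only the top subsets per round by
IG (ties: lexicographic gene tuple) to bound the combinatorial growth; set
it to `None` to keep every passing subset. An empty acceptance round halts
the entire search.

The trace records each round's accepted subsets, the best-performing
component (ties: lowest lexicographic gene tuple), per-round evaluation
counts, and the config echo; IG is displayed to 4 decimals and CE to 2.
Runs are byte-identical under a fixed matrix, labels, config and seed.

**On best-of-round monotonicity.** Acceptance guarantees each child
improves on its parents by ≥ ψ relative, so the best-of-round IG is
non-decreasing *whenever the previous best's lineage survives*. When the
top subset has no accepted extension its path halts (the subset remains a
candidate for the overall best), and the next round's best — drawn from
weaker lineages — can legitimately be lower. The overall best subset is
the maximum-IG subset across all rounds (ties: earliest round, then lowest
gene tuple).

Guideline settings for an M-gene matrix with pool size K: N in
[⌊ln K⌋, ⌊2·ln K⌋], δ = ⌊ln M⌋, ψ in 1–3%, K about 1.5% of M (rounded to
tens). At microarray scale (M = 22283, K = 300) these give N ∈ [5, 11],
δ = 10.

## Input handling

GEO series-matrix files (optionally gzipped) are parsed directly:
`!Sample_*` lines populate per-sample metadata, the table between the
begin/end markers becomes the genes × samples matrix, and "null"/"NA"/empty
cells become NaN (rejected by default at discretization time; per-gene
median imputation is a flag). Probes are additionally V-coded "V1".."VM" by
row order; V-codes are identifiers assigned once from the full file and are
preserved under gene subsetting, so a pool or trace entry keeps its
original code. Plain TSV matrices with a separate two-column label file are
supported symmetrically, with order-independent sample alignment and full
float round-tripping. Class labels come from a metadata field through an
ordered pattern → class mapping (first match wins; unmatched samples are
dropped with a warning).

## Synthetic benchmark

`simulate_dataset` generates a two-class cohort with known per-gene roles:

* **null genes** ~ Normal(base_mean, noise_sd²), class-independent;
* **marginal genes**: the second class is shifted by `s`·noise_sd
  (default s = 2, giving a single-gene IG around 0.37 bits at the default
  cohort size);
* **XOR pairs**: each gene takes a latent low/high state (separation
  3·noise_sd between state means), gene 1's state a fair coin per sample
  and gene 2's state chosen so the XOR of states equals the class, then
  flipped for a 5% label-noise fraction. Each gene's marginal distribution
  is therefore exactly class-independent while the exact 4-cell join
  carries ≈ 1 − H(0.05) ≈ 0.71 bits. Latent states are exposed as ground
  truth.

Defaults are 30 samples per class, 100 null genes, one marginal gene and
one XOR pair, on a log2-intensity-like scale (base mean 8, noise sd 1 —
typical magnitudes for processed two-channel/oligo array data). An optional
log-normal mode exponentiates to an intensity scale. The generator does not
emulate probe-level artifacts, batch effects, missingness patterns or
survival outcomes, so passing recovery tests demonstrate the algorithm's
statistical behaviour, not robustness to real-world technical noise.

`score_recovery` compares a trace's best subset with the planted gene set
(per-gene membership flags, precision, recall).

## Known limitations

* **The filter stage is blind to pure synergy.** Stage 1 ranks genes by
  single-gene IG, so a gene whose information is *entirely* interactive
  (e.g. an XOR-pair member, marginal IG ≈ 0) enters the candidate pool only
  by chance when K < M. On the default benchmark (K = 50 of 103 genes) each
  XOR member makes the pool roughly half the time, capping end-to-end pair
  recovery near 20–25% regardless of how well the growth stage works; the
  recovery experiment in the acceptance suite measures and reports exactly
  this. Raising K toward M removes the ceiling at quadratic cost in FCM
  evaluations.
* In-sample IG is an optimistically biased estimate under subset selection:
  with tens of samples and thousands of candidate subsets, the best
  noise-plus-marginal subsets can approach genuinely synergistic ones.
  The beam cap and the occupancy-capped cluster count bound, but do not
  eliminate, this effect; reported CE values are in-sample quantities, not
  generalization estimates.
* Multi-class labels are supported by all formulas, but the default
  discretization settings (2 EM components, n_classes^|S| cells) were
  chosen with binary grading in mind.
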