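# igselect

Entropy-based selection of *synergistic* gene subsets from expression data.

Most filter-style feature selection for transcriptomics scores genes one at a
time, which makes it blind to genes that are only informative in combination.
`igselect` implements a discretization-based selection algorithm for
two-class (or multi-class) expression cohorts — e.g. grading grade-III vs
grade-IV glioma from microarray profiles — that explicitly scores gene
*subsets*:

1. **Filter.** Every gene is discretized on its own by a one-dimensional
   Gaussian-mixture EM fit; the maximum-posterior component codes are scored
   against the class label C by information gain,
   IG(C, A) = H(C) − H(C|A) (bits). The top K genes form the candidate
   pool U.
2. **Seed.** The N best candidates launch independent search paths as
   singleton subsets (round 1).
3. **Grow.** For up to δ rounds, every retained subset S is extended by every
   pool gene y ∉ S. The block S∪{y} is re-discretized *jointly* by fuzzy
   c-means (Bezdek), and the child is accepted when its IG improves on its
   parent's by at least the width threshold ψ (relative improvement,
   ΔIG/IG(S) ≥ ψ). A round that accepts nothing ends the search.

Each round is reported with its best-performing subset, its discrimination
power IG (bits) and its classification effectiveness
CE = IG(S)/H(C) × 100%, where the label entropy H(C) is the upper bound any
subset can reach (CE = 100% ⇔ the discretized subset separates the classes
perfectly). For the 26/59 grade-III/IV cohort, H(C) ≈ 0.8884 bits.

Parameter guidelines for an M-gene matrix: K ≈ 1–10% of M, N between
⌊ln K⌋ and ⌊2·ln K⌋, δ = ⌊ln M⌋, ψ ≈ 1–3%.

The package also ships a seed-controlled synthetic-data generator that
plants known structure — null genes, marginally informative genes, and XOR
gene pairs that are individually silent but jointly discriminative — so the
whole pipeline is testable without downloading anything.

## Worked example

```python
from igselect import GeneSubsetSelector, SearchConfig, simulate_dataset

ds = simulate_dataset(seed=11)   # 100 nulls + 1 marginal gene + 1 XOR pair
cfg = SearchConfig(k=50, n_seeds=3, psi=0.02, delta=3, seed=11)
res = GeneSubsetSelector(ds.expression, ds.labels, cfg).fit()
print(res.summary())
```

prints

```
Gene subset selection
============================================================
Samples: 60   Genes: 103   Classes: III/IV
Label entropy H(C): 1.0000 bits
K=50  N=3  psi=0.02  delta=3  seed=11

Round  Best-performing component  IG      CE
--------------------------------------------
1      V101                       0.3664  36.64%
2      V26∪V101                   0.5049  50.49%
3      V14∪V94∪V101               0.5730  57.30%
4      V26∪V42∪V57∪V101           0.6198  61.98%

Best subset: V26∪V42∪V57∪V101
  IG = 0.6198 bits   CE = 61.98%
```

Reading this: the balanced 30/30 cohort carries H(C) = 1 bit of class
uncertainty. Round 1's best single gene is V101 — the planted marginal gene
(genes are V-coded by row order, so gene index 100 is "V101") — whose
EM-discretized codes recover 0.3664 bits (36.64% of the attainable
information). Each later round extends the retained subsets by one gene,
re-discretizes the block with fuzzy c-means, and keeps only extensions that
improve IG by ≥ 2%; by round 4 the best four-gene subset explains 61.98% of
the label entropy. `res.round_frame()` returns the same table as a
DataFrame, `res.to_json(path)` the full per-round trace.

The same run from the shell:

```bash
igselect simulate --seed 11 --out sim/
igselect select --input sim/matrix.tsv --labels sim/labels.tsv \
    --k 50 --n-seeds 3 --psi 0.02 --delta 3 --seed 11 --out run/
igselect suggest --total-genes 22283 --candidates 300   # N range [5, 11], delta 10
```

`igselect select` also reads GEO series-matrix files directly
(`--input GSE4412_series_matrix.txt.gz --label-field characteristics_ch1
--label-map "grade: III=III" --label-map "grade: IV=IV"`), assigning the
sequential V1..VM probe codes on load.

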