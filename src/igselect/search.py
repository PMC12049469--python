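"""Width/depth-controlled heuristic search for synergistic gene subsets.

Three stages:

1. **Filter** — every gene is discretized by a per-gene Gaussian-mixture EM
   and scored by information gain against the sample label; the top K genes
   form the candidate pool U.
2. **Seed** — the N best candidates become singleton subsets, each launching
   an independent search path (round 1).
3. **Grow** — for up to ``delta`` rounds, every retained subset S is extended
   by every pool gene y not already in S; the extended block is re-discretized
   by fuzzy c-means and the child is accepted when its IG improves on the
   parent's by at least the width threshold psi (relative by default:
   (IG_new - IG_S)/IG_S >= psi). An empty acceptance round halts the search.

Parameter guidelines for a matrix of M genes with pool size K:
N in [floor(ln K), floor(2 ln K)], delta = floor(ln M), psi in 1-3%.

The per-round trace mirrors the field's standard report: round index, best
performing subset, its IG (bits, 4 d.p. for display) and CE (%, 2 d.p.).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .discretize import EmSettings, FcmSettings, em_discretize, fcm_discretize
from .geo_io import ExpressionMatrix
from .infotheory import (
    LabelVector,
    ScoredSubset,
    classification_effectiveness,
    information_gain,
    shannon_entropy,
)

__all__ = [
    "SearchConfig",
    "CandidatePool",
    "SearchTrace",
    "RoundRecord",
    "filter_candidates",
    "seed_starters",
    "expand_round",
    "run_selection",
    "suggest_parameters",
    "default_pool_size",
]


class DegenerateLabelsError(ValueError):
    """Labels contain a single class; nothing can be discriminated."""


@dataclass(frozen=True)
class SearchConfig:
    """Parameters of the three-stage selection run.

    k: candidate-pool size K (default: ~1.5% of the gene count, see
        :func:`default_pool_size`).
    n_seeds: number N of top candidates launching search paths.
    psi: width threshold — minimum relative IG improvement (fraction) a
        child must deliver over its parent; ``psi_absolute=True`` switches
        to an absolute-Delta-IG threshold instead.
    delta: depth — maximum number of expansion rounds; the largest subset
        reachable has delta + 1 genes.
    beam_cap: optional cap on subsets retained per round (top by IG); the
        unbounded variant keeps every passing subset but can grow
        combinatorially.
    """

    k: Optional[int] = None
    n_seeds: int = 5
    psi: float = 0.02
    delta: int = 9
    beam_cap: Optional[int] = 200
    psi_absolute: bool = False
    em: EmSettings = field(default_factory=EmSettings)
    fcm: FcmSettings = field(default_factory=FcmSettings)
    seed: int = 0

    def __post_init__(self):
        if self.psi < 0:
            raise ValueError("psi must be non-negative")
        if self.delta < 0:
            raise ValueError("delta must be non-negative")
        if self.n_seeds < 1:
            raise ValueError("n_seeds must be positive")
        if self.k is not None and self.k < self.n_seeds:
            raise ValueError("need n_seeds <= k")
        if self.beam_cap is not None and self.beam_cap < self.n_seeds:
            raise ValueError("beam_cap must be >= n_seeds")


@dataclass(frozen=True)
class CandidatePool:
    """Top-K genes by single-gene EM-based IG, sorted descending."""

    gene_indices: tuple  # into the full matrix, IG-descending
    scores: tuple  # aligned with gene_indices

    def __post_init__(self):
        if len(self.gene_indices) != len(self.scores):
            raise ValueError("indices and scores must align")
        s = np.asarray(self.scores, dtype=float)
        if not np.isfinite(s).all():
            raise ValueError("scores must be finite")
        if len(s) > 1 and (np.diff(s) > 1e-12).any():
            raise ValueError("scores must be sorted descending")

    def __len__(self) -> int:
        return len(self.gene_indices)


@dataclass(frozen=True)
class RoundRecord:
    """One search round: the accepted set A_i and its best component."""

    round_index: int  # 1-based; subsets have round_index genes
    subsets: tuple  # of ScoredSubset, IG-descending
    best: ScoredSubset
    n_evaluated: int
    n_accepted: int


@dataclass(frozen=True)
class SearchTrace:
    rounds: tuple  # of RoundRecord
    label_entropy: float
    config: SearchConfig
    pool: CandidatePool
    v_codes: tuple = ()  # full-matrix V-codes, for reporting
    probe_ids: tuple = ()

    @property
    def best_subset(self) -> ScoredSubset:
        """Overall best subset across rounds (ties: earlier round, then
        lowest lexicographic gene tuple)."""
        best = None
        for rec in self.rounds:
            if best is None or rec.best.ig > best.ig + 1e-12:
                best = rec.best
        return best

    def names_for(self, subset: ScoredSubset) -> tuple:
        if not self.v_codes:
            return tuple(str(g) for g in subset.genes)
        return tuple(self.v_codes[g] for g in subset.genes)

    def to_dict(self) -> dict:
        """JSON-serializable trace (rounds, subsets with V-codes, IG, CE)."""
        def sub(s: ScoredSubset) -> dict:
            d = {"genes": list(s.genes), "ig": round(s.ig, 4), "ce": round(s.ce, 2)}
            if self.v_codes:
                d["v_codes"] = list(self.names_for(s))
            if self.probe_ids:
                d["probe_ids"] = [self.probe_ids[g] for g in s.genes]
            return d

        return {
            "label_entropy": round(self.label_entropy, 4),
            "config": {
                "k": self.config.k,
                "n_seeds": self.config.n_seeds,
                "psi": self.config.psi,
                "delta": self.config.delta,
                "beam_cap": self.config.beam_cap,
                "psi_absolute": self.config.psi_absolute,
                "seed": self.config.seed,
                "em_components": self.config.em.n_components,
                "fcm_clusters": self.config.fcm.c,
                "fcm_m": self.config.fcm.m,
            },
            "rounds": [
                {
                    "round": rec.round_index,
                    "best": sub(rec.best),
                    "n_evaluated": rec.n_evaluated,
                    "n_accepted": rec.n_accepted,
                    "subsets": [sub(s) for s in rec.subsets],
                }
                for rec in self.rounds
            ],
            "best_subset": sub(self.best_subset),
        }

    def summary_rows(self) -> list:
        """Per-round report rows: (round, component names, IG, CE)."""
        return [
            (
                rec.round_index,
                "∪".join(self.names_for(rec.best)),
                f"{rec.best.ig:.4f}",
                f"{rec.best.ce:.2f}%",
            )
            for rec in self.rounds
        ]

    def summary(self) -> str:
        header = ("Round", "Best-performing component", "IG", "CE")
        rows = [header] + [tuple(str(c) for c in r) for r in self.summary_rows()]
        widths = [max(len(r[i]) for r in rows) for i in range(4)]
        lines = ["  ".join(c.ljust(w) for c, w in zip(r, widths)).rstrip() for r in rows]
        lines.insert(1, "-" * len(lines[0]))
        return "\n".join(lines)


def default_pool_size(n_genes: int) -> int:
    """1.5% of the gene count, rounded to the nearest 10 (min 10)."""
    return max(10, int(round(n_genes * 0.015 / 10.0)) * 10)


def suggest_parameters(m_total: int, k: int) -> Tuple[int, int, int]:
    """Guideline settings (N_min, N_max, delta) for M genes and pool size K.

    N should lie in [floor(ln K), floor(2 ln K)]; delta = floor(ln M).
    """
    if k < 2:
        raise ValueError("pool size K must be at least 2")
    if m_total < k:
        raise ValueError("need M >= K")
    return (
        int(math.floor(math.log(k))),
        int(math.floor(2.0 * math.log(k))),
        int(math.floor(math.log(m_total))),
    )


def _check_labels(labels: LabelVector) -> float:
    h = shannon_entropy(labels)
    if len(labels.classes) < 2 or h <= 0:
        raise DegenerateLabelsError("labels must contain at least two classes")
    return h


def filter_candidates(
    expr: ExpressionMatrix, labels: LabelVector, config: SearchConfig
) -> CandidatePool:
    """Stage 1: score every gene by EM-discretized IG; keep the top K.

    Ties in IG are broken by ascending gene index, so duplicated rows rank
    in file order and runs are reproducible.
    """
    _check_labels(labels)
    if expr.n_samples != len(labels):
        raise ValueError("matrix samples and labels must align")
    m = expr.n_genes
    k = config.k if config.k is not None else default_pool_size(m)
    if not 1 <= k <= m:
        raise ValueError(f"K={k} must lie in [1, M={m}]")
    em = config.em
    scores = np.empty(m)
    for g in range(m):
        feat = em_discretize(
            expr.gene(g),
            n_components=em.n_components,
            seed=config.seed,
            max_iter=em.max_iter,
            tol=em.tol,
        ).assignments
        scores[g] = information_gain(labels, feat)
    order = np.lexsort((np.arange(m), -scores))[:k]
    return CandidatePool(
        gene_indices=tuple(int(g) for g in order),
        scores=tuple(float(scores[g]) for g in order),
    )


def seed_starters(pool: CandidatePool, n_seeds: int, label_entropy: float) -> Tuple[ScoredSubset, ...]:
    """Stage 2: the N top-IG pool genes as singleton subsets (A_1)."""
    if n_seeds < 1 or n_seeds > len(pool):
        raise ValueError(f"N={n_seeds} must lie in [1, |U|={len(pool)}]")
    return tuple(
        ScoredSubset(
            genes=(pool.gene_indices[i],),
            ig=pool.scores[i],
            ce=classification_effectiveness(pool.scores[i], label_entropy),
        )
        for i in range(n_seeds)
    )


def _accepts(parent_ig: float, child_ig: float, config: SearchConfig) -> bool:
    if config.psi_absolute:
        return child_ig - parent_ig >= config.psi - 1e-12
    if parent_ig <= 0:
        return child_ig > 0
    return (child_ig - parent_ig) / parent_ig >= config.psi - 1e-12


def expand_round(
    current: Sequence[ScoredSubset],
    pool: CandidatePool,
    expr: ExpressionMatrix,
    labels: LabelVector,
    config: SearchConfig,
    label_entropy: Optional[float] = None,
    _fcm_cache: Optional[Dict[tuple, float]] = None,
) -> Tuple[Tuple[ScoredSubset, ...], int]:
    """One growth round: extend every subset by every pool gene, score the
    fuzzy-c-means re-discretization, keep the children that clear psi.

    Duplicate children (same gene set via different parents) are
    canonicalized by sorted indices and evaluated once; the acceptance test
    uses the best (highest-IG) parent among those proposing the set. With a
    beam cap, only the top ``beam_cap`` children by IG are retained
    (ties: lexicographic gene tuple). Returns ``(children, n_evaluated)``;
    an empty result signals path termination to the caller.
    """
    if not current:
        raise ValueError("current round must be non-empty")
    h = label_entropy if label_entropy is not None else _check_labels(labels)
    cache: Dict[tuple, float] = _fcm_cache if _fcm_cache is not None else {}

    # best proposing parent per canonical child set
    proposals: Dict[tuple, float] = {}
    for s in current:
        sset = set(s.genes)
        for y in pool.gene_indices:
            if y in sset:
                continue
            child = tuple(sorted(sset | {y}))
            prev = proposals.get(child)
            if prev is None or s.ig > prev:
                proposals[child] = s.ig

    n_evaluated = 0
    accepted: List[ScoredSubset] = []
    for child, parent_ig in sorted(proposals.items()):
        ig = cache.get(child)
        if ig is None:
            feat = fcm_discretize(
                expr.block(child), config.fcm, seed=config.seed,
                n_classes=len(labels.classes),
            )
            ig = information_gain(labels, feat)
            cache[child] = ig
            n_evaluated += 1
        if _accepts(parent_ig, ig, config):
            accepted.append(
                ScoredSubset(genes=child, ig=ig, ce=classification_effectiveness(ig, h))
            )

    accepted.sort(key=lambda s: (-s.ig, s.genes))
    if config.beam_cap is not None:
        accepted = accepted[: config.beam_cap]
    return tuple(accepted), n_evaluated


def _best_of(subsets: Sequence[ScoredSubset]) -> ScoredSubset:
    # max IG; ties by lowest lexicographic sorted gene tuple
    return min(subsets, key=lambda s: (-s.ig, s.genes))


def run_selection(
    expr: ExpressionMatrix, labels: LabelVector, config: Optional[SearchConfig] = None
) -> SearchTrace:
    """Run the full three-stage selection and return the per-round trace.

    Round 1 holds the N seed singletons (scored by their stage-1 EM-based
    IG); rounds 2..delta+1 hold fuzzy-c-means-scored growing subsets. The
    loop stops early when a round accepts nothing. The trace is fully
    deterministic given the matrix, labels and config (including seed).
    """
    config = config or SearchConfig()
    h = _check_labels(labels)
    pool = filter_candidates(expr, labels, config)
    current = seed_starters(pool, config.n_seeds, h)
    rounds = [
        RoundRecord(
            round_index=1,
            subsets=tuple(sorted(current, key=lambda s: (-s.ig, s.genes))),
            best=_best_of(current),
            n_evaluated=expr.n_genes,
            n_accepted=len(current),
        )
    ]
    cache: Dict[tuple, float] = {}
    for i in range(1, config.delta + 1):
        children, n_eval = expand_round(
            current, pool, expr, labels, config, label_entropy=h, _fcm_cache=cache
        )
        if not children:
            break
        rounds.append(
            RoundRecord(
                round_index=i + 1,
                subsets=children,
                best=_best_of(children),
                n_evaluated=n_eval,
                n_accepted=len(children),
            )
        )
        current = children
    return SearchTrace(
        rounds=tuple(rounds),
        label_entropy=h,
        config=config,
        pool=pool,
        v_codes=expr.v_codes,
        probe_ids=expr.probe_ids,
    )
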