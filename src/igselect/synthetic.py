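"""Seed-controlled synthetic expression data with known ground truth.

The generator emulates the statistical structure a two-class microarray
selection task presents: a large background of class-independent noise
genes, a few marginally informative genes whose class-conditional means are
shifted, and planted synergistic gene pairs that are individually
uninformative but jointly discriminative (an XOR pattern of low/high
expression states determines the class, up to a small label-noise rate).

Defaults describe a compact two-class cohort (30 samples per class, 100
null genes, one marginal gene shifted by 2 noise-sd, one XOR pair) on a
log2-intensity-like scale (base mean 8, noise sd 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .geo_io import ExpressionMatrix
from .infotheory import LabelVector, ScoredSubset

__all__ = ["SimulationSpec", "SimulatedDataset", "simulate_dataset", "score_recovery", "RecoveryReport"]

#: separation between the "low" and "high" XOR states, in units of noise_sd
XOR_STATE_SEPARATION = 3.0


@dataclass(frozen=True)
class SimulationSpec:
    """Ground-truth layout of a simulated two-class expression matrix.

    marginal_genes: per-gene mean shifts, in units of noise_sd, applied to
        the second class.
    synergy_groups: each entry plants one XOR pair — two genes whose
        low/high states jointly (but not marginally) determine the class;
        the entry value is the label-noise rate (fraction of samples whose
        class contradicts the XOR rule).
    """

    n_per_class: int = 30
    m_null: int = 100
    marginal_genes: tuple = (2.0,)
    synergy_groups: tuple = (0.05,)
    noise_sd: float = 1.0
    base_mean: float = 8.0
    log_normal: bool = False
    seed: int = 0
    class_names: tuple = ("III", "IV")

    def __post_init__(self):
        object.__setattr__(self, "marginal_genes", tuple(self.marginal_genes))
        object.__setattr__(self, "synergy_groups", tuple(self.synergy_groups))
        if self.n_per_class < 1 or self.m_null < 0:
            raise ValueError("counts must be non-negative (n_per_class >= 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.total_genes < 1:
            raise ValueError("spec must contain at least one gene")
        if any(not 0 <= r < 0.5 for r in self.synergy_groups):
            raise ValueError("synergy label-noise rates must lie in [0, 0.5)")
        if self.synergy_groups and self.n_per_class < 4:
            raise ValueError("XOR groups need at least 4 samples per class")

    @property
    def total_genes(self) -> int:
        return self.m_null + len(self.marginal_genes) + 2 * len(self.synergy_groups)


@dataclass(frozen=True)
class SimulatedDataset:
    expression: ExpressionMatrix
    labels: LabelVector
    truth: tuple  # per-gene role: "null" | "marginal" | "synergy:<g>"
    latent_states: dict = field(default_factory=dict)  # synergy gene -> 0/1 state per sample

    def genes_with_role(self, prefix: str) -> tuple:
        return tuple(i for i, t in enumerate(self.truth) if t.startswith(prefix))

    @property
    def planted_genes(self) -> tuple:
        """All non-null gene indices."""
        return tuple(i for i, t in enumerate(self.truth) if t != "null")


def simulate_dataset(spec: Optional[SimulationSpec] = None, **kwargs) -> SimulatedDataset:
    """Generate a two-class expression matrix with planted structure.

    Gene layout (row order): null genes, then marginal genes, then synergy
    pairs. Null genes draw Normal(base_mean, noise_sd^2) independently of
    class. A marginal gene with shift s adds s * noise_sd to every
    second-class sample. Each synergy pair assigns gene 1 a fair-coin
    low/high state per sample and sets gene 2's state so that the XOR of
    states equals the class indicator, then flips gene 2's state for a
    label-noise fraction of samples — so each gene's marginal distribution
    is class-independent while the 4-cell joint is strongly discriminative.
    Entirely determined by ``spec.seed``.
    """
    if spec is None:
        spec = SimulationSpec(**kwargs)
    elif kwargs:
        raise TypeError("pass either a SimulationSpec or keyword fields, not both")
    rng = np.random.default_rng(int(spec.seed) % (2**31))
    n = 2 * spec.n_per_class
    class_idx = np.repeat([0, 1], spec.n_per_class)

    rows = []
    truth = []
    rows.append(rng.normal(spec.base_mean, spec.noise_sd, size=(spec.m_null, n)))
    truth += ["null"] * spec.m_null

    for s in spec.marginal_genes:
        g = rng.normal(spec.base_mean, spec.noise_sd, size=n)
        g[class_idx == 1] += s * spec.noise_sd
        rows.append(g[None, :])
        truth.append("marginal")

    sep = XOR_STATE_SEPARATION * spec.noise_sd
    latent = {}
    for gi, noise_rate in enumerate(spec.synergy_groups):
        state1 = rng.integers(0, 2, size=n)
        state2 = state1 ^ class_idx  # XOR(state1, state2) == class
        flip = rng.random(n) < noise_rate
        state2 = np.where(flip, 1 - state2, state2)
        g1 = rng.normal(spec.base_mean + sep * state1, spec.noise_sd)
        g2 = rng.normal(spec.base_mean + sep * state2, spec.noise_sd)
        base = len(truth)
        latent[base] = state1.copy()
        latent[base + 1] = state2.copy()
        rows.append(np.vstack([g1, g2]))
        truth += [f"synergy:{gi}", f"synergy:{gi}"]

    values = np.vstack(rows)
    if spec.log_normal:
        values = 2.0**values  # intensity scale; discretization is scale-robust
    m = values.shape[0]
    expr = ExpressionMatrix(
        values=values,
        probe_ids=tuple(f"sim_probe_{i + 1}" for i in range(m)),
        sample_ids=tuple(f"sample_{j + 1}" for j in range(n)),
    )
    labels = LabelVector([spec.class_names[c] for c in class_idx])
    return SimulatedDataset(
        expression=expr, labels=labels, truth=tuple(truth), latent_states=latent
    )


@dataclass(frozen=True)
class RecoveryReport:
    recovered: dict  # planted gene index -> bool (in the final best subset)
    precision: float
    recall: float
    best_subset: tuple


def score_recovery(trace, truth: Sequence[str]) -> RecoveryReport:
    """Compare a search trace's best subset with the planted gene set.

    Precision and recall are of the final best subset against all planted
    (non-null) genes; per-gene flags report membership individually.
    """
    planted = tuple(i for i, t in enumerate(truth) if t != "null")
    best = trace.best_subset if hasattr(trace, "best_subset") else trace
    genes = set(best.genes if isinstance(best, ScoredSubset) else best)
    hits = genes & set(planted)
    return RecoveryReport(
        recovered={g: g in genes for g in planted},
        precision=len(hits) / len(genes) if genes else 0.0,
        recall=len(hits) / len(planted) if planted else 0.0,
        best_subset=tuple(sorted(genes)),
    )
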