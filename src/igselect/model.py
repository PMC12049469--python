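"""Model/Results front end over the subset-selection machinery.

``GeneSubsetSelector`` is constructed from data (an expression matrix plus a
label per sample) and configuration; ``fit()`` executes the three-stage
search and returns a ``SelectionResults`` carrying the per-round trace, the
best subset, and a printable summary table.
"""

from __future__ import annotations

import json
from typing import Optional, Sequence

import pandas as pd

from .geo_io import ExpressionMatrix
from .infotheory import LabelVector, ScoredSubset
from .search import SearchConfig, SearchTrace, run_selection, suggest_parameters

__all__ = ["GeneSubsetSelector", "SelectionResults"]


class GeneSubsetSelector:
    """Selects synergistic gene subsets from an expression matrix.

    Parameters
    ----------
    expression : ExpressionMatrix
        Genes x samples matrix.
    labels : LabelVector
        Class label per sample (two classes in the typical tumour-grading
        task; the formulas support more).
    config : SearchConfig, optional
        Search parameters (K, N, psi, delta, discretization settings, seed).
    """

    def __init__(
        self,
        expression: ExpressionMatrix,
        labels: LabelVector,
        config: Optional[SearchConfig] = None,
    ):
        if expression.n_samples != len(labels):
            raise ValueError(
                f"{expression.n_samples} matrix samples vs {len(labels)} labels"
            )
        self.expression = expression
        self.labels = labels
        self.config = config or SearchConfig()

    @classmethod
    def from_dataframe(
        cls,
        frame: pd.DataFrame,
        labels: Sequence,
        config: Optional[SearchConfig] = None,
    ) -> "GeneSubsetSelector":
        """Build from a genes-as-rows DataFrame and a per-column label sequence."""
        expr = ExpressionMatrix(
            values=frame.to_numpy(dtype=float),
            probe_ids=tuple(str(p) for p in frame.index),
            sample_ids=tuple(str(s) for s in frame.columns),
        )
        return cls(expr, LabelVector(labels), config)

    def suggested_parameters(self) -> tuple:
        """(N_min, N_max, delta) guideline for this matrix and pool size."""
        k = self.config.k or max(2, int(round(self.expression.n_genes * 0.015 / 10.0)) * 10)
        return suggest_parameters(self.expression.n_genes, k)

    def fit(self) -> "SelectionResults":
        trace = run_selection(self.expression, self.labels, self.config)
        return SelectionResults(self, trace)


class SelectionResults:
    """Results of a selection run: trace, best subset, summary table."""

    def __init__(self, model: GeneSubsetSelector, trace: SearchTrace):
        self.model = model
        self.trace = trace

    @property
    def label_entropy(self) -> float:
        """H(C), the upper bound for any subset's information gain (bits)."""
        return self.trace.label_entropy

    @property
    def best_subset(self) -> ScoredSubset:
        return self.trace.best_subset

    @property
    def best_genes(self) -> tuple:
        """V-codes of the overall best subset."""
        return self.trace.names_for(self.best_subset)

    def round_frame(self) -> pd.DataFrame:
        """Per-round report as a DataFrame (round, best component, IG, CE)."""
        rows = self.trace.summary_rows()
        return pd.DataFrame(
            rows, columns=["round", "best_component", "ig_bits", "ce_percent"]
        )

    def summary(self) -> str:
        t = self.trace
        best = self.best_subset
        lines = [
            "Gene subset selection",
            "=" * 60,
            f"Samples: {self.model.expression.n_samples}   "
            f"Genes: {self.model.expression.n_genes}   "
            f"Classes: {'/'.join(str(c) for c in self.model.labels.classes)}",
            f"Label entropy H(C): {t.label_entropy:.4f} bits",
            f"K={len(t.pool)}  N={t.config.n_seeds}  psi={t.config.psi}  "
            f"delta={t.config.delta}  seed={t.config.seed}",
            "",
            t.summary(),
            "",
            f"Best subset: {'∪'.join(self.best_genes)}",
            f"  IG = {best.ig:.4f} bits   CE = {best.ce:.2f}%",
        ]
        return "\n".join(lines)

    def to_json(self, path=None) -> str:
        payload = json.dumps(self.trace.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload

    def to_tsv(self, path) -> None:
        """Write the per-round summary as a tab-separated table."""
        self.round_frame().to_csv(path, sep="\t", index=False)
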