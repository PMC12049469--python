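"""Three-stage subset search: candidate filtering, seeding, width/depth
controlled growth, trace audits and the parameter guideline."""

import numpy as np
import pytest

from igselect import (
    SearchConfig,
    SimulationSpec,
    expand_round,
    filter_candidates,
    run_selection,
    seed_starters,
    shannon_entropy,
    simulate_dataset,
    suggest_parameters,
)
from igselect.geo_io import ExpressionMatrix
from igselect.infotheory import LabelVector
from igselect.search import DegenerateLabelsError, default_pool_size


@pytest.fixture(scope="module")
def planted():
    return simulate_dataset(SimulationSpec(m_null=60, seed=3))


class TestSuggestParameters:
    def test_glioma_scale_guidelines(self):
        assert suggest_parameters(22283, 300) == (5, 11, 10)

    def test_small_pool(self):
        n_min, n_max, delta = suggest_parameters(200, 20)
        assert (n_min, n_max) == (2, 5)
        assert delta == 5

    def test_rejects_tiny_pool(self):
        with pytest.raises(ValueError):
            suggest_parameters(100, 1)

    def test_default_pool_size_fraction(self):
        assert default_pool_size(22283) == 330  # ~1.5%, nearest 10
        assert default_pool_size(100) == 10


class TestFilterCandidates:
    def test_planted_marginals_recovered(self):
        # five marginally informative genes among 200 nulls all reach the pool
        ds = simulate_dataset(
            SimulationSpec(m_null=200, marginal_genes=(2.0,) * 5, synergy_groups=(), seed=1)
        )
        pool = filter_candidates(ds.expression, ds.labels, SearchConfig(k=20, seed=1))
        marginals = set(ds.genes_with_role("marginal"))
        assert marginals <= set(pool.gene_indices)

    def test_k_equals_m_ranks_everything(self, planted):
        cfg = SearchConfig(k=planted.expression.n_genes, seed=0)
        pool = filter_candidates(planted.expression, planted.labels, cfg)
        assert len(pool) == planted.expression.n_genes
        assert list(pool.scores) == sorted(pool.scores, reverse=True)

    def test_duplicate_rows_tie_break_by_index(self):
        rng = np.random.default_rng(0)
        row = rng.normal(0, 1, 20)
        expr = ExpressionMatrix(
            values=np.vstack([row, row, row]),
            probe_ids=("a", "b", "c"),
            sample_ids=tuple(f"s{i}" for i in range(20)),
        )
        labels = LabelVector([0, 1] * 10)
        pool = filter_candidates(expr, labels, SearchConfig(k=3, n_seeds=3, seed=0))
        assert pool.gene_indices == (0, 1, 2)
        assert pool.scores[0] == pool.scores[1] == pool.scores[2]

    def test_single_class_rejected(self, planted):
        labels = LabelVector(["x"] * planted.expression.n_samples)
        with pytest.raises(DegenerateLabelsError):
            filter_candidates(planted.expression, labels, SearchConfig(k=5, seed=0))


class TestSeedStarters:
    def test_top_n_singletons(self, planted):
        pool = filter_candidates(planted.expression, planted.labels, SearchConfig(k=10, seed=0))
        h = shannon_entropy(planted.labels)
        seeds = seed_starters(pool, 3, h)
        assert [s.genes[0] for s in seeds] == list(pool.gene_indices[:3])
        assert all(s.ce == pytest.approx(s.ig / h * 100) for s in seeds)

    def test_n_too_large_rejected(self, planted):
        pool = filter_candidates(planted.expression, planted.labels, SearchConfig(k=5, seed=0))
        with pytest.raises(ValueError):
            seed_starters(pool, 6, 1.0)

    def test_strongest_marginal_among_seeds(self, planted):
        pool = filter_candidates(planted.expression, planted.labels, SearchConfig(k=20, seed=0))
        seeds = seed_starters(pool, 5, shannon_entropy(planted.labels))
        marginal = planted.genes_with_role("marginal")[0]
        assert marginal in {s.genes[0] for s in seeds}


class TestExpandRound:
    def test_huge_psi_halts(self, planted):
        cfg = SearchConfig(k=10, n_seeds=2, psi=50.0, delta=2, seed=0)
        pool = filter_candidates(planted.expression, planted.labels, cfg)
        h = shannon_entropy(planted.labels)
        seeds = seed_starters(pool, 2, h)
        children, _ = expand_round(seeds, pool, planted.expression, planted.labels, cfg)
        assert children == ()

    def test_duplicate_children_canonicalized(self, planted):
        cfg = SearchConfig(k=6, n_seeds=6, psi=0.0, delta=1, seed=0)
        pool = filter_candidates(planted.expression, planted.labels, cfg)
        h = shannon_entropy(planted.labels)
        seeds = seed_starters(pool, 6, h)
        children, n_eval = expand_round(seeds, pool, planted.expression, planted.labels, cfg)
        sets = [c.genes for c in children]
        assert len(sets) == len(set(sets))
        # every unordered pair evaluated once: C(6,2) = 15
        assert n_eval == 15

    def test_children_have_parent_plus_one(self, planted):
        cfg = SearchConfig(k=8, n_seeds=3, psi=0.0, delta=1, seed=0)
        pool = filter_candidates(planted.expression, planted.labels, cfg)
        seeds = seed_starters(pool, 3, shannon_entropy(planted.labels))
        children, _ = expand_round(seeds, pool, planted.expression, planted.labels, cfg)
        seed_sets = [set(s.genes) for s in seeds]
        for c in children:
            assert len(c.genes) == 2
            assert any(s < set(c.genes) for s in seed_sets)

    def test_synergy_partner_joins_anchor(self):
        # an anchor seed plus the XOR partner scores far above anchor alone
        ds = simulate_dataset(SimulationSpec(m_null=30, seed=12))
        cfg = SearchConfig(k=ds.expression.n_genes, n_seeds=3, psi=0.02, delta=2, seed=12)
        trace = run_selection(ds.expression, ds.labels, cfg)
        g1, g2 = ds.genes_with_role("synergy")
        final = trace.rounds[-1].subsets
        assert any({g1, g2} <= set(s.genes) for s in final)


class TestRunSelection:
    def test_delta_zero_only_seeds(self, planted):
        cfg = SearchConfig(k=10, n_seeds=4, delta=0, seed=0)
        trace = run_selection(planted.expression, planted.labels, cfg)
        assert len(trace.rounds) == 1
        assert trace.rounds[0].n_accepted == 4

    def test_full_determinism(self, planted):
        cfg = SearchConfig(k=15, n_seeds=3, psi=0.01, delta=2, seed=42)
        a = run_selection(planted.expression, planted.labels, cfg)
        b = run_selection(planted.expression, planted.labels, cfg)
        assert a.to_dict() == b.to_dict()

    def test_trace_audit_improvement_and_monotonicity(self, planted):
        cfg = SearchConfig(k=20, n_seeds=3, psi=0.02, delta=3, seed=1)
        trace = run_selection(planted.expression, planted.labels, cfg)
        audit_trace(trace, cfg.psi)

    def test_ce_consistent_with_label_entropy(self, planted):
        cfg = SearchConfig(k=12, n_seeds=2, psi=0.02, delta=2, seed=9)
        trace = run_selection(planted.expression, planted.labels, cfg)
        for rec in trace.rounds:
            for s in rec.subsets:
                assert s.ce == pytest.approx(s.ig / trace.label_entropy * 100, abs=1e-9)

    def test_round_sizes_and_containment(self, planted):
        cfg = SearchConfig(k=15, n_seeds=3, psi=0.0, delta=2, beam_cap=10, seed=4)
        trace = run_selection(planted.expression, planted.labels, cfg)
        for i, rec in enumerate(trace.rounds):
            assert rec.round_index == i + 1
            assert all(s.size == i + 1 for s in rec.subsets)
            assert len(rec.subsets) <= (3 if i == 0 else 10)
            if i:
                prev = [set(s.genes) for s in trace.rounds[i - 1].subsets]
                for s in rec.subsets:
                    assert any(p < set(s.genes) for p in prev)

    def test_summary_table_shape(self, planted):
        cfg = SearchConfig(k=10, n_seeds=2, delta=1, seed=0)
        trace = run_selection(planted.expression, planted.labels, cfg)
        text = trace.summary()
        assert "Round" in text and "IG" in text
        assert len(text.splitlines()) == len(trace.rounds) + 2


def audit_trace(trace, psi, require_monotone_best=False):
    """Shared audit: every accepted child improves on each of its parents in
    the previous round by at least psi relative (acceptance tests against the
    strongest parent, so all weaker parents are cleared too). Best-of-round
    IG is guaranteed non-decreasing whenever the previous best's lineage
    survives; ``require_monotone_best`` additionally demands it
    unconditionally."""
    for i in range(1, len(trace.rounds)):
        prev = {s.genes: s.ig for s in trace.rounds[i - 1].subsets}
        best_prev_survived = False
        best_prev = trace.rounds[i - 1].best
        for child in trace.rounds[i].subsets:
            parents = [
                ig for genes, ig in prev.items() if set(genes) < set(child.genes)
            ]
            assert parents, "child without parent in previous round"
            required = max(p * (1 + psi) if p > 0 else 0.0 for p in parents)
            assert child.ig >= required - 1e-9
            if set(best_prev.genes) < set(child.genes):
                best_prev_survived = True
        if require_monotone_best or best_prev_survived:
            assert trace.rounds[i].best.ig >= trace.rounds[i - 1].best.ig - 1e-9
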