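import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cfscreen.annotations import CofactorRecord, GenomeBackground
from cfscreen.enrichment import (
    adjust_pvalues,
    essentiality_enrichment,
    hypergeom_upper_tail,
    promoter_enrichment,
    tissue_enrichment,
)
from cfscreen.hitcalling import InteractionCall
from cfscreen.network import build_network
from oracles import hypergeom_tail_exact


def record(gene_id, categories=("remodeler",), tissues=(), essential=False, in_library=True):
    return CofactorRecord(
        gene_id=gene_id,
        name=gene_id,
        categories=frozenset(categories),
        tissues=frozenset(tissues),
        essential=essential,
        clone_source="orfeome" if in_library else "none",
    )


def edge(reg, prom, sign=-1):
    return InteractionCall(reg, prom, sign, 3, 2, 2, final=True)


class TestHypergeomUpperTail:
    def test_k_zero_is_one(self):
        assert hypergeom_upper_tail(0, 5, 3, 10) == 1.0

    def test_certain_event(self):
        assert hypergeom_upper_tail(4, 4, 10, 10) == pytest.approx(1.0)

    def test_small_case_matches_exact_enumeration(self):
        assert hypergeom_upper_tail(3, 4, 5, 10) == pytest.approx(
            hypergeom_tail_exact(3, 4, 5, 10), abs=1e-12
        )

    def test_bound_violation_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_upper_tail(6, 4, 5, 10)  # k > min(n, K)
        with pytest.raises(ValueError):
            hypergeom_upper_tail(1, 11, 5, 10)  # K > N

    @given(st.data())
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_matches_exact_enumeration_random_tuples(self, data):
        N = data.draw(st.integers(1, 30))
        K = data.draw(st.integers(0, N))
        n = data.draw(st.integers(0, N))
        k = data.draw(st.integers(0, min(n, K)))
        assert hypergeom_upper_tail(k, K, n, N) == pytest.approx(
            hypergeom_tail_exact(k, K, n, N), abs=1e-12
        )

    def test_genome_scale_stability(self):
        p = hypergeom_upper_tail(300, 6000, 335, 19987)
        assert 0.0 < p < 1e-100  # deep tail still finite and positive


class TestAdjustPvalues:
    def test_single_p_unchanged(self):
        assert adjust_pvalues([0.03])[0] == pytest.approx(0.03)

    def test_all_equal_is_fixed_point(self):
        out = adjust_pvalues([0.2, 0.2, 0.2])
        assert np.allclose(out, 0.2)

    def test_bh_step_up_hand_computed(self):
        # sorted p (0.01, 0.02, 0.03, 0.04), m=4:
        # p*m/i = (0.04, 0.04, 0.04, 0.04) after the step-up minimum
        out = adjust_pvalues([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_monotone_in_raw_order(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(1e-6, 1, size=50)
        adj = adjust_pvalues(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)
        assert np.all(adj >= p - 1e-12)

    def test_identity_method(self):
        p = [0.01, 0.5]
        assert list(adjust_pvalues(p, "none")) == p

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_pvalues([0.0, 0.5])


class TestEssentialityEnrichment:
    def test_fully_essential_group_is_significant(self):
        recs = [record(f"g{i}", essential=True) for i in range(10)]
        bg = GenomeBackground(n_genes=19987, n_essential=9993)
        (res,) = essentiality_enrichment(recs, bg, include_overall=False)
        assert res.p_raw == pytest.approx(
            hypergeom_tail_exact(10, 9993, 10, 19987), rel=1e-9
        )
        assert res.p_raw < 0.05
        assert res.percent_fg == 100

    def test_zero_essential_group_p_is_one(self):
        recs = [record(f"g{i}") for i in range(10)]
        bg = GenomeBackground(n_genes=1000, n_essential=300)
        (res,) = essentiality_enrichment(recs, bg, include_overall=False)
        assert res.p_raw == 1.0

    def test_overall_row_deduplicates_genes(self):
        recs = [
            record("g1", categories=("remodeler", "bromodomain"), essential=True),
            record("g2"),
        ]
        bg = GenomeBackground(n_genes=1000, n_essential=300)
        res = essentiality_enrichment(recs, bg, deduplicate_overall=True)
        overall = [r for r in res if r.foreground_label == "all_CFs"][0]
        assert overall.n == 2 and overall.k == 1
        res2 = essentiality_enrichment(recs, bg, deduplicate_overall=False)
        overall2 = [r for r in res2 if r.foreground_label == "all_CFs"][0]
        assert overall2.n == 3 and overall2.k == 2

    def test_order_invariance(self):
        recs = [record(f"g{i}", essential=(i % 3 == 0)) for i in range(12)]
        bg = GenomeBackground(n_genes=1000, n_essential=300)
        a = essentiality_enrichment(recs, bg)
        b = essentiality_enrichment(list(reversed(recs)), bg)
        assert a == b


class TestPromoterEnrichment:
    def _records(self):
        group = [record(f"g{i}", categories=("target-group",)) for i in range(5)]
        rest = [record(f"x{i}", categories=("other",)) for i in range(20)]
        return group + rest

    def test_perfectly_matching_group_minimises_p(self):
        recs = self._records()
        calls = [edge(f"g{i}", "p1") for i in range(5)]
        net = build_network(calls, promoters=["p1"])
        res = promoter_enrichment(net, recs, "decrease")
        by_label = {r.foreground_label: r for r in res}
        target = by_label["category:target-group"]
        assert target.k == 5 and target.n == 5 and target.K == 5 and target.N == 25
        assert target.p_raw == pytest.approx(
            hypergeom_tail_exact(5, 5, 5, 25), abs=1e-12
        )
        assert target.p_raw == min(r.p_raw for r in res)

    def test_no_overlap_gives_p_one(self):
        recs = self._records()
        calls = [edge(f"x{i}", "p1") for i in range(3)]
        net = build_network(calls, promoters=["p1"])
        res = promoter_enrichment(net, recs, "decrease")
        target = [r for r in res if r.foreground_label == "category:target-group"][0]
        assert target.k == 0 and target.p_raw == 1.0

    def test_symmetric_in_group_and_hitset(self):
        # swapping the roles of the group and the hit set preserves p
        assert hypergeom_upper_tail(3, 8, 6, 40) == pytest.approx(
            hypergeom_upper_tail(3, 6, 8, 40), abs=1e-15
        )

    def test_direction_filtering(self):
        recs = self._records()
        calls = [edge("g0", "p1", 1), edge("g1", "p1", -1)]
        net = build_network(calls, promoters=["p1"])
        res_inc = promoter_enrichment(net, recs, "increase")
        target = [r for r in res_inc if r.foreground_label == "category:target-group"][0]
        assert target.n == 1 and target.k == 1

    def test_unknown_direction_rejected(self):
        net = build_network([], promoters=["p1"])
        with pytest.raises(ValueError, match="direction"):
            promoter_enrichment(net, self._records(), "sideways")


class TestTissueEnrichment:
    def test_all_expressed_gives_p_one(self):
        recs = [record(f"g{i}", tissues=("intestine",)) for i in range(10)]
        net = build_network([edge("g0", "p1"), edge("g1", "p1")], promoters=["p1"])
        res = tissue_enrichment(net, recs, "intestine")
        assert res.K == res.N and res.p_raw == pytest.approx(1.0)

    def test_no_interacting_expressed_gives_p_one(self):
        recs = [record("g0", tissues=("neuron",))] + [
            record(f"g{i}", tissues=("intestine",)) for i in range(1, 10)
        ]
        net = build_network([edge("g0", "p1")], promoters=["p1"])
        res = tissue_enrichment(net, recs, "neuron")
        # the single interactor IS neuron-expressed here; flip the query
        res2 = tissue_enrichment(net, recs, "intestine")
        assert res2.k == 0 and res2.p_raw == 1.0

    def test_unknown_tissue_rejected(self):
        recs = [record("g0", tissues=("intestine",))]
        net = build_network([], promoters=["p1"])
        with pytest.raises(LookupError):
            tissue_enrichment(net, recs, "gonad sheath")

    def test_planted_tissue_effect_detected(self):
        # intestine-expressed regulators get 3x the interaction probability
        rng = np.random.default_rng(99)
        hits = 0
        for _ in range(20):
            recs, calls = [], []
            for i in range(335):
                expressed = i < 200
                recs.append(
                    record(f"g{i:03d}", tissues=("intestine",) if expressed else ("neuron",))
                )
                d = 0.099 if expressed else 0.033
                for j in range(19):
                    if rng.random() < d:
                        calls.append(edge(f"g{i:03d}", f"p{j:02d}"))
            net = build_network(calls, promoters=[f"p{j:02d}" for j in range(19)])
            res = tissue_enrichment(net, recs, "intestine")
            hits += res.p_raw < 0.05
        assert hits >= 18
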