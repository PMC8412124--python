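"""Hypergeometric tail, overlap counting, calibration and BH adjustment."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from regulonscan.enrichment import (
    bh_adjust,
    calibrate_universe,
    enrich_tfs,
    hypergeom_upper_tail,
    matches_printed,
    regulon_overlap,
)
from regulonscan.model import (
    CandidateTF,
    DEGene,
    DETable,
    DomainError,
    Regulon,
    RegulonDB,
    SpeciesMismatchError,
    TailConvention,
)

GE, GT = TailConvention.GE, TailConvention.GT


def enumerate_tail(N, K, n, k, convention):
    """Brute-force oracle: count draws of size n with enough annotated items."""
    annotated = set(range(K))
    total = hits = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        overlap = len(annotated.intersection(draw))
        if (overlap >= k) if convention is GE else (overlap > k):
            hits += 1
    return hits / total


class TestHypergeomUpperTail:
    def test_whole_sample_space(self):
        assert hypergeom_upper_tail(10, 5, 4, 0, GE) == 1.0

    def test_max_overlap_matches_enumeration(self):
        # 5 of C(10,4)=210 draws contain all 4 annotated items
        assert hypergeom_upper_tail(10, 5, 4, 4, GE) == pytest.approx(5 / 210)

    def test_strict_tail_empty_sum_is_zero(self):
        assert hypergeom_upper_tail(10, 5, 4, 4, GT) == 0.0

    @pytest.mark.parametrize("convention", [GE, GT])
    @pytest.mark.parametrize("N,K,n", [(7, 3, 4), (9, 5, 3), (10, 4, 6)])
    def test_matches_enumeration_oracle(self, N, K, n, convention):
        for k in range(min(K, n) + 1):
            expected = enumerate_tail(N, K, n, k, convention)
            assert hypergeom_upper_tail(N, K, n, k, convention) == pytest.approx(
                expected, abs=1e-12
            )

    def test_matches_scipy_survival_function(self):
        from scipy.stats import hypergeom

        for N, K, n in [(1000, 100, 50), (17000, 6020, 269)]:
            for k in (0, 5, 20):
                assert hypergeom_upper_tail(N, K, n, k, GE) == pytest.approx(
                    float(hypergeom.sf(k - 1, N, K, n)), rel=1e-9
                )

    def test_extreme_tail_keeps_relative_precision(self):
        # magnitudes around 1e-23 must survive with >= 3 significant digits
        p = hypergeom_upper_tail(20475, 6170, 1820, 737, GE)
        assert 1e-24 < p < 1e-21
        assert f"{p:.2e}" == "4.31e-23"

    def test_precondition_violations_named(self):
        with pytest.raises(DomainError, match="k <= min"):
            hypergeom_upper_tail(10, 3, 4, 5)
        with pytest.raises(DomainError, match="K <= N"):
            hypergeom_upper_tail(10, 11, 4, 2)
        with pytest.raises(DomainError, match="n <= N"):
            hypergeom_upper_tail(10, 3, 11, 2)

    @given(
        st.integers(min_value=1, max_value=60).flatmap(
            lambda N: st.tuples(
                st.just(N),
                st.integers(0, N),
                st.integers(0, N),
            )
        )
    )
    @settings(max_examples=60, deadline=None)
    def test_tail_properties(self, NKn):
        N, K, n = NKn
        ks = range(min(K, n) + 1)
        ge = [hypergeom_upper_tail(N, K, n, k, GE) for k in ks]
        gt = [hypergeom_upper_tail(N, K, n, k, GT) for k in ks]
        # monotone decreasing in k; GE >= GT; GE(k) == GT(k-1)
        assert all(a >= b - 1e-12 for a, b in zip(ge, ge[1:]))
        assert all(a >= b - 1e-12 for a, b in zip(ge, gt))
        for k in list(ks)[1:]:
            assert ge[k] == pytest.approx(gt[k - 1], rel=1e-9)
        # symmetry in (K, n) and point masses summing to one
        assert hypergeom_upper_tail(N, n, K, min(K, n) // 2) == pytest.approx(
            hypergeom_upper_tail(N, K, n, min(K, n) // 2), rel=1e-9
        )
        masses = [ge[k] - gt[k] for k in ks]
        assert sum(masses) == pytest.approx(1.0, abs=1e-12)


def _de(species="human", genes=()):
    return DETable(species=species, genes=list(genes))


def _gene(gid, lfc=1.0, padj=0.01):
    return DEGene(gene_id=gid, log2fc=lfc, padj=padj)


class TestRegulonOverlap:
    def test_counts_by_hand(self):
        de = _de(genes=[_gene("A", padj=0.5), _gene("B", padj=0.01),
                        _gene("D", padj=0.5)])
        reg = Regulon(tf_id="TF", targets=frozenset({"A", "B", "C"}),
                      species="human")
        assert regulon_overlap(reg, de) == (2, 1)

    def test_no_expressed_targets(self):
        de = _de(genes=[_gene("X")])
        reg = Regulon(tf_id="TF", targets=frozenset({"A"}), species="human")
        assert regulon_overlap(reg, de) == (0, 0)

    def test_all_targets_upregulated(self):
        de = _de(genes=[_gene("A"), _gene("B")])
        reg = Regulon(tf_id="TF", targets=frozenset({"A", "B"}), species="human")
        K, k = regulon_overlap(reg, de)
        assert K == k == 2

    def test_species_mismatch(self):
        de = _de(species="zebrafish", genes=[_gene("a")])
        reg = Regulon(tf_id="TF", targets=frozenset({"a"}), species="human")
        with pytest.raises(SpeciesMismatchError):
            regulon_overlap(reg, de)


class TestEnrichTfs:
    def test_single_tf_enumeration_value(self):
        # targets {A,B} all upregulated among 2 of 4 expressed: p = 1/C(4,2)
        de = _de(genes=[_gene("A"), _gene("B"),
                        _gene("C", padj=0.5), _gene("D", padj=0.5)])
        db = RegulonDB(
            regulons={"TF": Regulon("TF", frozenset({"A", "B"}), "human")},
            species="human",
        )
        cand = CandidateTF("TF", 1.0, 0.01, True, False)
        (row,) = enrich_tfs([cand], db, de)
        assert (row.K_expressed, row.k_up, row.n_up, row.N_universe) == (2, 2, 2, 4)
        assert row.p == pytest.approx(1 / 6)

    def test_zero_overlap_gives_p_one(self):
        de = _de(genes=[_gene("A"), _gene("B", padj=0.5)])
        db = RegulonDB(
            regulons={"TF": Regulon("TF", frozenset({"B"}), "human")},
            species="human",
        )
        (row,) = enrich_tfs([CandidateTF("TF", 1.0, 0.01, True, False)], db, de)
        assert row.p == 1.0 and not row.enriched

    def test_identical_counts_identical_p(self, table1):
        cands = [CandidateTF(tf, 1.0, 0.01, True, False) for tf in ("SPI1", "SPI1")]
        r1, r2 = enrich_tfs(cands, table1.human_db, table1.human_de)
        assert r1.p == r2.p

    def test_missing_regulon_is_contract_violation(self):
        de = _de(genes=[_gene("A")])
        db = RegulonDB(regulons={}, species="human")
        with pytest.raises(KeyError):
            enrich_tfs([CandidateTF("TF", 1.0, 0.01, True, False)], db, de)


class TestCalibrateUniverse:
    def test_forward_then_invert_recovers_universe(self):
        p = hypergeom_upper_tail(17000, 6020, 269, 136, GE)
        printed = f"{p:.2e}"
        res = calibrate_universe(6020, 136, 269, printed,
                                 n_range=(16000, 18000), conventions=(GE,))
        assert any(lo <= 17000 <= hi for lo, hi in res.windows[GE])

    def test_uninformative_anchor_flagged(self):
        res = calibrate_universe(50, 0, 20, "1.0", n_range=(100, 200))
        assert res.uninformative
        assert res.windows[GE] == [(100, 200)]

    def test_no_solution_is_explicit(self):
        res = calibrate_universe(50, 20, 20, "0.9", n_range=(100, 200))
        assert not res.has_solution
        assert res.n_chosen is None

    def test_matches_printed_precision_rules(self):
        assert matches_printed(2.104e-7, "2.10E-07")
        assert not matches_printed(2.2e-7, "2.10E-07")
        assert matches_printed(0.00093, "0.0009")
        assert matches_printed(0.0765, "0.08")
        assert not matches_printed(0.086, "0.08")


class TestBHAdjust:
    def test_hand_examples(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])
        assert bh_adjust([0.5, 0.01]) == pytest.approx([0.5, 0.02])
        assert bh_adjust([0.2]) == [0.2]

    def test_out_of_range_rejected(self):
        with pytest.raises(DomainError):
            bh_adjust([0.5, 1.2])

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(0)
        p = rng.uniform(size=40)
        expected = multipletests(p, method="fdr_bh")[1]
        assert bh_adjust(p.tolist()) == pytest.approx(expected.tolist())

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_monotone_and_dominating_on_sorted(self, pvals):
        pvals = sorted(pvals)
        adj = bh_adjust(pvals)
        assert all(a <= b + 1e-12 for a, b in zip(adj, adj[1:]))
        assert all(q >= p - 1e-12 for q, p in zip(adj, pvals))
        assert all(q <= 1.0 for q in adj)
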