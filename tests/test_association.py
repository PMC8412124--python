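"""Spearman rho, exact permutation p-values, and the correlation stages."""

import math

import numpy as np
import pandas as pd
import pytest

from regulonscan.association import (
    correlate_covariate,
    correlate_pair,
    correlate_tf_targets,
    spearman_p,
    spearman_rho,
)
from regulonscan.model import DomainError, ExpressionMatrix
from regulonscan.simulate import SyntheticConfig, TFSpec, generate_dataset


class TestSpearmanRho:
    @pytest.mark.parametrize(
        "x,y,expected",
        [
            ([1, 2, 3], [10, 20, 30], 1.0),
            ([1, 2, 3], [3, 2, 1], -1.0),
            # midranks [1, 2.5, 2.5, 4] vs [1, 3, 2, 4]:
            # Pearson = 4.5 / sqrt(4.5 * 5) = 0.94868...
            ([1, 2, 2, 4], [1, 3, 2, 4], 4.5 / math.sqrt(22.5)),
        ],
    )
    def test_hand_values(self, x, y, expected):
        assert spearman_rho(x, y) == pytest.approx(expected)

    def test_matches_scipy(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=30), rng.normal(size=30)
        from scipy.stats import spearmanr

        assert spearman_rho(x, y) == pytest.approx(spearmanr(x, y).statistic)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=15), rng.normal(size=15)
        rho = spearman_rho(x, y)
        assert spearman_rho(np.exp(x), y) == pytest.approx(rho)
        assert spearman_rho(x, 3 * y + 7) == pytest.approx(rho)

    def test_constant_vector_rejected(self):
        with pytest.raises(DomainError, match="constant"):
            spearman_rho([1, 1, 1], [1, 2, 3])


class TestSpearmanP:
    def test_perfect_correlation_n3(self):
        # of the 3! rank permutations, |rho| = 1 occurs twice
        assert spearman_p(1.0, 3, "exact") == pytest.approx(2 / 6)

    def test_zero_rho_is_never_significant(self):
        assert spearman_p(0.0, 5, "exact") == 1.0

    def test_exact_matches_independent_enumeration(self):
        """Oracle: rho recomputed per permutation via a rank Pearson formula."""
        import itertools

        n = 6
        base = np.arange(n, dtype=float)
        rhos = [
            float(np.corrcoef(base, np.asarray(perm, dtype=float))[0, 1])
            for perm in itertools.permutations(range(n))
        ]
        for observed in (0.3, 0.7, 0.9, 1.0):
            expected = np.mean([abs(r) >= observed - 1e-12 for r in rhos])
            assert spearman_p(observed, n, "exact") == pytest.approx(expected)

    def test_exact_close_to_t_approximation_at_n10(self):
        for rho in (0.2, 0.4, 0.6, 0.8):
            exact = spearman_p(rho, 10, "exact")
            approx = spearman_p(rho, 10, "approx")
            assert abs(exact - approx) < 0.02

    def test_monte_carlo_within_three_standard_errors(self):
        n, rho = 8, 0.55
        exact = spearman_p(rho, n, "exact")
        mc8 = _mc_p(rho, n, 100_000, seed=0)
        se = math.sqrt(exact * (1 - exact) / 100_000)
        assert abs(mc8 - exact) <= 3 * se

    def test_too_small_n_rejected(self):
        with pytest.raises(DomainError):
            spearman_p(0.5, 2, "exact")


def _mc_p(rho, n, draws, seed):
    rng = np.random.default_rng(seed)
    base = np.arange(n, dtype=float)
    hits = 0
    for _ in range(draws):
        perm = rng.permutation(n).astype(float)
        r = 1 - 6 * ((perm - base) ** 2).sum() / (n * (n * n - 1))
        hits += abs(r) >= abs(rho) - 1e-12
    return hits / draws


def _matrix(values: dict, groups=None, ages=None):
    df = pd.DataFrame(values)
    n = len(df)
    meta = pd.DataFrame(
        {
            "group": groups or ["case"] * n,
            "age": ages if ages is not None else list(range(n)),
        },
        index=df.index,
    )
    return ExpressionMatrix(values=df, metadata=meta)


class TestCorrelateTfTargets:
    def test_identical_target_passes(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(1, 10, size=8)
        expr = _matrix({"TF": x, "T1": x.copy()})
        rows, passing, warns = correlate_tf_targets(expr, "TF", ["T1"])
        assert passing == 1
        assert rows[0].rho == pytest.approx(1.0)

    def test_absent_target_warns_absent_tf_raises(self):
        expr = _matrix({"TF": [1.0, 2, 3, 4]})
        _, _, warns = correlate_tf_targets(expr, "TF", ["NOPE"])
        assert any("nope" in w for w in warns)
        with pytest.raises(KeyError):
            correlate_tf_targets(expr, "MISSING", ["TF"])

    def test_planted_latent_factor_targets_mostly_pass(self):
        """Targets loaded on the TF's latent factor at 0.9 clear rho > 0.70."""
        cfg = SyntheticConfig(seed=11, n_genes=3000, n_up=100,
                              tf_list=[TFSpec("TF1", 200, 6.0)],
                              n_case=12, n_control=10, latent_loading=0.9)
        ds = generate_dataset(cfg)
        targets = sorted(ds.regulons.get("TF1").targets)[:100]
        rows, passing, _ = correlate_tf_targets(ds.expression, "TF1", targets)
        assert passing / len(rows) >= 0.8

    def test_independent_genes_rarely_pass(self):
        cfg = SyntheticConfig(seed=11, n_genes=3000, n_up=100,
                              tf_list=[TFSpec("TF1", 200, 6.0)],
                              n_case=12, n_control=10, latent_loading=0.9)
        ds = generate_dataset(cfg)
        non_targets = [
            g.gene_id for g in ds.de_table.genes
            if g.gene_id.casefold() not in ds.regulons.get("TF1").targets
        ][1:101]
        rows, passing, _ = correlate_tf_targets(ds.expression, "TF1", non_targets)
        assert passing / len(rows) <= 0.1


class TestCorrelateCovariate:
    def test_monotone_age_gives_rho_one(self):
        ages = [10, 20, 30, 40, 50]
        expr = _matrix({"G": [1.0, 2, 3, 4, 5]}, ages=ages)
        row = correlate_covariate(expr, "G", "age", group="case")
        assert row.rho == pytest.approx(1.0)

    def test_two_sample_group_rejected(self):
        expr = _matrix({"G": [1.0, 2, 3]}, groups=["case", "case", "control"],
                       ages=[1, 2, 3])
        with pytest.raises(DomainError, match="n >= 3"):
            correlate_covariate(expr, "G", "age", group="control")

    def test_missing_covariate_lists_samples(self):
        expr = _matrix({"G": [1.0, 2, 3, 4]}, ages=[1, 2, np.nan, 4])
        with pytest.raises(DomainError, match="missing"):
            correlate_covariate(expr, "G", "age")

    def test_recovers_planted_rank_correlation(self):
        """Bivariate-normal pairs tuned to Spearman 0.7 at n=10: the mean
        recovered rho over 200 seeded replicates is within 0.05 and most
        single replicates within 0.25."""
        target = 0.7
        pearson = 2 * math.sin(math.pi * target / 6)
        rng = np.random.default_rng(42)
        rhos = []
        for _ in range(200):
            z = rng.standard_normal((10, 2))
            x = z[:, 0]
            y = pearson * z[:, 0] + math.sqrt(1 - pearson**2) * z[:, 1]
            expr = _matrix({"G": np.exp(x)}, ages=y)
            rhos.append(correlate_covariate(expr, "G", "age").rho)
        rhos = np.asarray(rhos)
        assert abs(rhos.mean() - target) < 0.05
        assert np.mean(np.abs(rhos - target) <= 0.25) >= 0.75


class TestTiesFallback:
    def test_ties_disable_exact_enumeration(self):
        warns: list[str] = []
        rho, p, method = correlate_pair([1, 2, 2, 4, 5], [5, 4, 3, 2, 1],
                                        warn_sink=warns)
        assert method == "t-approximation"
        assert warns and "ties" in warns[0]

    def test_tie_free_small_n_uses_exact(self):
        rho, p, method = correlate_pair([1, 2, 3, 4, 5], [5, 4, 3, 2, 1])
        assert method == "exact-permutation"
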