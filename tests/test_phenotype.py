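from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu, rankdata

from fentonflux.phenotype import (
    bh_adjust,
    correlate_phenotype,
    growth_rate,
    load_phenotype_table,
    mann_whitney,
    relative_fenton_level,
    stratify_quartiles,
)


class TestRelativeFentonLevel:
    def test_equal_outfluxes(self):
        flux = {m: 1.0 for m in ["a", "b", "c", "d", "Fenton reaction"]}
        assert relative_fenton_level(flux) == pytest.approx(0.2)

    def test_fenton_only(self):
        flux = {"a": 0.0, "b": 0.0, "c": 0.0, "d": 0.0, "Fenton reaction": 3.0}
        assert relative_fenton_level(flux) == 1.0

    def test_weighted_case(self):
        flux = {"a": 1.0, "b": 1.0, "c": 1.0, "d": 1.0, "Fenton reaction": 6.0}
        assert relative_fenton_level(flux) == pytest.approx(0.6)

    @pytest.mark.parametrize("scale", [0.5, 3.0, 1e6])
    def test_scale_invariance(self, scale):
        flux = {"a": 0.2, "b": 1.4, "c": 0.7, "d": 2.0, "Fenton reaction": 1.1}
        scaled = {k: v * scale for k, v in flux.items()}
        assert relative_fenton_level(scaled) == pytest.approx(
            relative_fenton_level(flux)
        )

    def test_all_zero_is_undefined(self):
        flux = {m: 0.0 for m in ["a", "b", "c", "d", "Fenton reaction"]}
        assert np.isnan(relative_fenton_level(flux))


class TestGrowthRate:
    def test_one_year_doubling(self):
        assert growth_rate(365.0) == 1.0

    def test_fast_doubling(self):
        assert growth_rate(10.0) == pytest.approx(36.5)

    def test_slower_doubling(self):
        assert growth_rate(103.0) == pytest.approx(3.544, abs=5e-4)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            growth_rate(0.0)

    def test_bundled_table_covers_eleven_subtypes(self):
        table = load_phenotype_table()
        assert len(table) == 11
        assert table.loc["COAD", "doubling_days"] == 10
        assert (table["doubling_days"] > 0).all()


class TestStratifyQuartiles:
    def test_top_and_bottom_quarters(self):
        values = pd.Series(
            range(1, 9), index=[f"s{i}" for i in range(1, 9)], dtype=float
        )
        high, low = stratify_quartiles(values, q=0.25)
        assert high == ["s8", "s7"]
        assert low == ["s1", "s2"]

    def test_half_split_partitions(self):
        values = pd.Series([4.0, 1.0, 3.0, 2.0], index=list("abcd"))
        high, low = stratify_quartiles(values, q=0.5)
        assert set(high) | set(low) == set("abcd")
        assert set(high).isdisjoint(low)

    def test_all_equal_is_deterministic_with_warning(self):
        values = pd.Series(1.0, index=list("dcba"))
        with pytest.warns(UserWarning):
            high, low = stratify_quartiles(values, q=0.5)
        assert low == ["a", "b"] and high == ["c", "d"]

    def test_sizes_and_disjointness(self):
        rng = np.random.default_rng(3)
        values = pd.Series(rng.normal(size=37), index=[f"x{i}" for i in range(37)])
        high, low = stratify_quartiles(values, q=0.25)
        assert len(high) == len(low) == 9
        assert set(high).isdisjoint(low)

    def test_too_small_cohort_rejected(self):
        with pytest.raises(ValueError):
            stratify_quartiles(pd.Series([1.0, 2.0], index=["a", "b"]), q=0.25)


def oracle_exact_p(a, b):
    """Full enumeration of rank assignments; independent of the implementation."""
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    n_a, n = len(a), len(pooled)
    u_obs = ranks[:n_a].sum() - n_a * (n_a + 1) / 2
    us = [
        ranks[list(idx)].sum() - n_a * (n_a + 1) / 2
        for idx in combinations(range(n), n_a)
    ]
    total = comb(n, n_a)
    lo = sum(u <= u_obs + 1e-9 for u in us) / total
    hi = sum(u >= u_obs - 1e-9 for u in us) / total
    return min(1.0, 2 * min(lo, hi))


class TestMannWhitney:
    def test_fully_separated_small_samples(self):
        u, p = mann_whitney([1, 2], [3, 4])
        assert u == 0.0
        assert p == pytest.approx(1 / 3)

    def test_identical_samples_give_half_umax(self):
        a = [1.0, 2.0, 3.0]
        u, _ = mann_whitney(a, a)
        assert u == len(a) * len(a) / 2

    def test_u_statistics_sum_to_nm(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            a = rng.integers(0, 5, size=7).astype(float)  # heavy ties
            b = rng.integers(0, 5, size=9).astype(float)
            u_a, _ = mann_whitney(a, b)
            u_b, _ = mann_whitney(b, a)
            assert u_a + u_b == len(a) * len(b)

    def test_exact_p_matches_enumeration_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(4):
            a = rng.normal(size=5)
            b = rng.normal(0.8, 1.0, size=6)
            _, p = mann_whitney(a, b)
            assert p == pytest.approx(oracle_exact_p(a, b))

    def test_exact_matches_scipy_without_ties(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=8), rng.normal(0.5, 1, size=8)
        _, p = mann_whitney(a, b)
        assert p == pytest.approx(mannwhitneyu(a, b, method="exact").pvalue)

    def test_normal_approximation_close_to_exact(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            a = rng.normal(size=8)
            b = rng.normal(0.5, 1.0, size=8)
            _, p_exact = mann_whitney(a, b)
            _, p_normal = mann_whitney(a, b, exact_limit=0)
            assert abs(p_exact - p_normal) < 0.02

    def test_large_sample_agrees_with_scipy_asymptotics(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=40)
        b = rng.normal(0.4, 1.0, size=35)
        _, p = mann_whitney(a, b)
        ref = mannwhitneyu(a, b, method="asymptotic").pvalue
        assert p == pytest.approx(ref, rel=1e-6)


class TestCorrelatePhenotype:
    def test_identity(self):
        x = [1.0, 2.0, 4.0, 8.0]
        r, _ = correlate_phenotype(x, x)
        assert r == pytest.approx(1.0)

    def test_moderate_correlation_significant_at_eleven_types(self):
        # construct two 11-vectors whose sample correlation is exactly 0.635
        rng = np.random.default_rng(5)
        x = rng.normal(size=11)
        e = rng.normal(size=11)
        xz = (x - x.mean()) / x.std()
        ez = e - e.mean()
        ez -= xz * (ez @ xz) / (xz @ xz)
        ez /= ez.std()
        target = 0.635
        y = target * xz + np.sqrt(1 - target**2) * ez
        r, p = correlate_phenotype(x, y)
        assert r == pytest.approx(0.635, abs=1e-9)
        assert p < 0.05

    def test_constant_phenotype_rejected(self):
        with pytest.raises(ValueError):
            correlate_phenotype([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])


class TestBhAdjust:
    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(6)
        p = rng.uniform(size=25)
        ours = bh_adjust(p)
        ref = multipletests(p, method="fdr_bh")[1]
        assert ours == pytest.approx(ref)
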