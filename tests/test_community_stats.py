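"""Diversity, rank tests, ordination and distribution summaries."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from prokmorph import (distribution_summary, kruskal_wallis, pca_ordination,
                       shannon_index, virus_prokaryote_ratio)


class TestShannon:
    def test_uniform_seven_categories(self):
        assert shannon_index({m: 10 for m in range(7)}) == pytest.approx(
            np.log2(7), rel=1e-12)

    def test_single_category_is_zero(self):
        assert shannon_index({"cocci": 42}) == 0.0

    def test_hand_computed_mixture(self):
        assert shannon_index([4, 4, 8]) == pytest.approx(1.5)

    def test_upper_bound_and_scale_invariance(self, rng):
        counts = rng.integers(1, 50, 6)
        h = shannon_index(counts)
        assert h <= np.log2(6) + 1e-12
        assert shannon_index(counts * 17) == pytest.approx(h, rel=1e-12)

    def test_natural_log_base(self):
        assert shannon_index([1, 1], base=np.e) == pytest.approx(np.log(2))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            shannon_index({})


def _oracle_h(groups):
    """Independent tie-corrected H from first principles."""
    pooled = np.concatenate(groups)
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(len(pooled))
    sorted_vals = pooled[order]
    i = 0
    while i < len(pooled):
        j = i
        while j < len(pooled) and sorted_vals[j] == sorted_vals[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0
        i = j
    n = len(pooled)
    start, stat = 0, 0.0
    for g in groups:
        stat += ranks[start:start + len(g)].sum() ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * stat - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    return h / (1 - np.sum(counts**3 - counts) / (n**3 - n))


class TestKruskalWallis:
    def test_identical_groups_give_zero_h_unit_p(self):
        r = kruskal_wallis([[1, 2, 3], [1, 2, 3]])
        assert r.statistic == pytest.approx(0.0, abs=1e-12)
        assert r.p_value == pytest.approx(1.0)

    def test_hand_ranked_separated_groups(self):
        r = kruskal_wallis([[1, 2, 3], [10, 11, 12]])
        assert r.statistic == pytest.approx(3.857, abs=1e-3)
        assert r.df == 1

    def test_matches_scipy_on_random_groups(self, rng):
        groups = [rng.normal(i, 1, 30) for i in range(3)]
        r = kruskal_wallis(groups)
        h, p = sps.kruskal(*groups)
        assert r.statistic == pytest.approx(h)
        assert r.p_value == pytest.approx(p)

    def test_statistic_matches_first_principles_oracle(self, rng):
        for _ in range(10):
            sizes = rng.integers(2, 4, size=3)
            groups = [rng.integers(0, 5, s).astype(float) for s in sizes]
            if np.ptp(np.concatenate(groups)) == 0:
                continue
            r = kruskal_wallis(groups)
            assert r.statistic == pytest.approx(_oracle_h(groups), abs=1e-10)

    def test_exact_permutation_p_matches_enumeration_oracle(self, rng):
        groups = [rng.normal(0, 1, 3), rng.normal(1.5, 1, 3), rng.normal(0.5, 1, 3)]
        r = kruskal_wallis(groups, p_method="exact")
        pooled = np.concatenate(groups)
        h_obs = _oracle_h(groups)
        count = total = 0
        # every distinct split of the pooled sample into groups of 3/3/3
        for first in itertools.combinations(range(9), 3):
            rest = [i for i in range(9) if i not in first]
            for second in itertools.combinations(rest, 3):
                third = [i for i in rest if i not in second]
                gs = [pooled[list(first)], pooled[list(second)], pooled[third]]
                total += 1
                if _oracle_h(gs) >= h_obs - 1e-12:
                    count += 1
        assert total == 1680
        assert r.p_value == pytest.approx(count / total, abs=1e-12)

    def test_row_order_invariance(self, rng):
        groups = [rng.normal(0, 1, 20), rng.normal(1, 1, 20)]
        shuffled = [g[rng.permutation(len(g))] for g in groups]
        assert kruskal_wallis(groups).statistic == pytest.approx(
            kruskal_wallis(shuffled).statistic)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2, 3]])
        with pytest.raises(ValueError):
            kruskal_wallis([[1.0], []])


class TestOrdination:
    def _matrix(self, rng, n=12, p=5):
        base = rng.normal(0, 1, (n, 2))
        mix = rng.normal(0, 1, (2, p))
        return pd.DataFrame(np.abs(base @ mix + rng.normal(0, 0.3, (n, p))) + 0.1,
                            columns=[f"v{i}" for i in range(p)])

    def test_variance_explained_sums_to_100(self, rng):
        res = pca_ordination(self._matrix(rng))
        assert res.variance_explained.sum() == pytest.approx(100.0)

    def test_reconstruction_from_all_components(self, rng):
        res = pca_ordination(self._matrix(rng))
        np.testing.assert_allclose(res.reconstruction(),
                                   res.transformed.to_numpy(), atol=1e-8)

    def test_loadings_orthonormal(self, rng):
        L = pca_ordination(self._matrix(rng)).loadings.to_numpy()
        np.testing.assert_allclose(L.T @ L, np.eye(L.shape[1]), atol=1e-8)

    def test_duplicated_samples_get_identical_scores(self, rng):
        df = self._matrix(rng)
        df2 = pd.concat([df, df.iloc[[0]]], ignore_index=True)
        res = pca_ordination(df2)
        np.testing.assert_allclose(res.scores.iloc[0], res.scores.iloc[-1],
                                   atol=1e-10)

    def test_rank_one_data_loads_on_single_component(self):
        x = np.linspace(1, 5, 10)
        df = pd.DataFrame({"a": x, "b": 2 * x})
        res = pca_ordination(df, transform=None)
        assert res.variance_explained[0] == pytest.approx(100.0)

    def test_row_order_invariance_of_variance(self, rng):
        df = self._matrix(rng)
        perm = df.sample(frac=1, random_state=1)
        np.testing.assert_allclose(
            pca_ordination(df).variance_explained,
            pca_ordination(perm).variance_explained, atol=1e-10)

    def test_constant_column_under_standardization_rejected(self, rng):
        df = self._matrix(rng)
        df["const"] = 3.0
        with pytest.raises(ValueError, match="const"):
            pca_ordination(df)

    def test_missing_rows_dropped_with_warning(self, rng, caplog):
        df = self._matrix(rng)
        df.iloc[0, 0] = np.nan
        with caplog.at_level("WARNING"):
            res = pca_ordination(df)
        assert len(res.scores) == len(df) - 1

    def test_cos2_rows_sum_to_one_for_standardized_data(self, rng):
        res = pca_ordination(self._matrix(rng))
        np.testing.assert_allclose(res.cos2.sum(axis=1), 1.0, atol=1e-8)


class TestDistributionSummary:
    def test_moments_match_direct_formulas(self, rng):
        x = rng.normal(3, 2, 500)
        s = distribution_summary(x)
        assert s.mean == pytest.approx(x.mean())
        assert s.sd == pytest.approx(x.std())
        assert s.median == pytest.approx(np.median(x))

    def test_density_integrates_to_one(self, rng):
        s = distribution_summary(rng.lognormal(-2, 0.5, 400))
        assert np.trapezoid(s.density, s.grid) == pytest.approx(1.0, abs=0.01)

    def test_bimodal_mixture_shows_two_modes(self, rng):
        x = np.concatenate([rng.normal(0.05, 0.01, 300),
                            rng.normal(0.25, 0.02, 300)])
        s = distribution_summary(x)
        d = s.density
        interior = (d[1:-1] > d[:-2]) & (d[1:-1] > d[2:])
        assert interior.sum() == 2

    def test_single_value_is_narrow_bump(self):
        s = distribution_summary([0.7])
        assert s.sd == 0.0
        assert s.grid[np.argmax(s.density)] == pytest.approx(0.7, rel=1e-2)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            distribution_summary([])


class TestVPR:
    def test_published_ratio_examples(self):
        assert virus_prokaryote_ratio(5e5, 1e6) == pytest.approx(0.5)
        assert virus_prokaryote_ratio(1.4e6, 1e6) == pytest.approx(1.4)
        assert virus_prokaryote_ratio(7e5, 7e5) == 1.0

    def test_zero_prokaryotes_rejected(self):
        with pytest.raises(ValueError):
            virus_prokaryote_ratio(1e5, 0.0)
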