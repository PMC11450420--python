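"""Tetrachoric estimation, Fisher-z pooling and the MDS layout."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import careclust as cc
from careclust.tetrachoric import (
    bvn_cdf,
    kruskal_stress,
    pair_table,
    tetrachoric_matrix,
)
from scipy import stats


class TestBvnCdf:
    @pytest.mark.parametrize("rho", [-0.9, -0.3, 0.0, 0.4, 0.95])
    def test_against_quadrature(self, rho):
        """Owen's-T evaluation matches direct 2-d quadrature of the
        bivariate normal density."""
        from scipy.integrate import dblquad

        for h, k in [(-0.5, 0.8), (0.0, 0.3), (1.2, 1.2), (-1.5, -0.2)]:
            direct, _ = dblquad(
                lambda y, x: stats.multivariate_normal.pdf(
                    [x, y], cov=[[1, rho], [rho, 1]]
                ),
                -8.0, h, -8.0, k, epsabs=1e-11,
            )
            assert bvn_cdf(h, k, rho) == pytest.approx(direct, abs=1e-9)

    def test_independence_factorises(self):
        assert bvn_cdf(0.7, -0.2, 0.0) == pytest.approx(
            stats.norm.cdf(0.7) * stats.norm.cdf(-0.2), abs=1e-12
        )


class TestTetrachoric:
    @pytest.mark.parametrize("rho", [-0.6, -0.2, 0.3, 0.5, 0.7])
    def test_median_split_closed_form(self, rho):
        """For median splits rho = sin(2 pi (p11 - 1/4)): exact-proportion
        tables recover the planted rho to 1e-3."""
        p11 = 0.25 + math.asin(rho) / (2 * math.pi)
        tab = np.array([[p11, 0.5 - p11], [0.5 - p11, p11]]) * 1e6
        assert abs(cc.tetrachoric(tab) - rho) < 1e-3

    @pytest.mark.parametrize("pa,pb", [(0.5, 0.5), (0.3, 0.7), (0.2, 0.4)])
    def test_independence_gives_zero(self, pa, pb):
        tab = np.array(
            [[(1 - pa) * (1 - pb), (1 - pa) * pb], [pa * (1 - pb), pa * pb]]
        ) * 1e6
        assert abs(cc.tetrachoric(tab)) < 1e-6

    def test_zero_margin_returns_nan(self):
        assert math.isnan(cc.tetrachoric(np.array([[30.0, 20.0], [0.0, 0.0]])))

    def test_zero_cell_correction_applied(self):
        rho = cc.tetrachoric(np.array([[40.0, 0.0], [5.0, 40.0]]))
        assert -0.999 <= rho <= 0.999 and np.isfinite(rho)

    @given(
        cells=st.tuples(*[st.integers(min_value=5, max_value=80)] * 4)
    )
    def test_transpose_symmetry_and_sign_flip(self, cells):
        tab = np.array(cells, dtype=float).reshape(2, 2)
        r = cc.tetrachoric(tab)
        assert cc.tetrachoric(tab.T) == pytest.approx(r, abs=1e-6)
        # swapping one variable's coding flips the sign exactly
        assert cc.tetrachoric(tab[::-1, :]) == pytest.approx(-r, abs=1e-6)


class TestPooledMatrix:
    def test_identical_imputations_equal_single_dataset(self, separable_imps):
        imps, _, _ = separable_imps  # completed copies are identical
        net = cc.pooled_matrix(imps)
        single = tetrachoric_matrix(imps.completed[0])
        assert np.allclose(net.rho, single, atol=1e-9, equal_nan=True)
        assert net.pooled_from == imps.m
        assert len(net.edge_list) == 13 * 12 // 2

    def test_planted_latent_correlation_recovered(self):
        """Two indicators thresholded from a shared latent normal with
        correlation 0.6 pool to within +-0.05."""
        rng = np.random.default_rng(3)
        n = 5000
        z = rng.multivariate_normal([0, 0], [[1, 0.6], [0.6, 1]], size=n)
        x = (z[:, 0] > stats.norm.ppf(0.4)).astype(np.int8)
        y = (z[:, 1] > stats.norm.ppf(0.6)).astype(np.int8)
        filler = (rng.random((n, 1)) < 0.5).astype(np.int8)
        values = np.column_stack([x, y, filler])
        from careclust.impute import ImputationSet

        imps = ImputationSet(
            completed=[values, values.copy()],
            episode_ids=np.arange(n).astype(object),
            indicator_names=("a", "b", "c"),
            m=2,
            rng_state={},
        )
        net = cc.pooled_matrix(imps)
        assert abs(net.rho[0, 1] - 0.6) < 0.05

    def test_strongest_edges_form_expected_blocks(self, complete_cohort):
        """On the default cohort the distress/low-QoL pair and the
        housing-NEET-benefits block are among the strongest edges."""
        mat = cc.derive_indicators(complete_cohort)
        filtered, _ = cc.exclusion_filter(mat)
        imps = cc.impute(filtered, m_count=2, seed=1)
        net = cc.pooled_matrix(imps)
        edges = net.edge_list.sort_values("rho", ascending=False).head(8)
        pairs = {frozenset((r.source, r.target)) for r in edges.itertuples()}
        assert frozenset(("distress", "low_qol")) in pairs
        psychosocial = {"housing", "neet", "eet_issue", "benefits"}
        assert any(p <= psychosocial for p in pairs)


class TestMdsLayout:
    def test_identity_rho_is_exchangeable(self):
        """Three mutually uncorrelated items embed as an equilateral
        triangle: all pairwise layout distances equal."""
        coords = cc.mds_layout(np.eye(3))
        d = np.sqrt(((coords[:, None] - coords[None, :]) ** 2).sum(-1))
        off = d[np.triu_indices(3, k=1)]
        assert np.allclose(coords.mean(axis=0), 0.0, atol=1e-9)
        assert off.max() - off.min() < 1e-9

    def test_perfectly_correlated_items_coincide(self):
        rho = np.eye(3)
        rho[0, 1] = rho[1, 0] = 1.0
        coords = cc.mds_layout(rho)
        assert np.allclose(coords[0], coords[1], atol=1e-8)

    def test_exactly_embeddable_structure_recovered(self):
        """A correlation matrix generated from planar coordinates is
        reproduced with near-zero stress."""
        rng = np.random.default_rng(7)
        theta = rng.uniform(0, 2 * np.pi, size=8)
        v = np.column_stack([np.cos(theta), np.sin(theta)])
        rho = v @ v.T  # unit diagonal, PSD; d = sqrt(2(1-rho)) is planar
        coords = cc.mds_layout(rho)
        assert kruskal_stress(rho, coords) < 1e-8

    def test_layout_fits_pooled_default_matrix(self, complete_cohort):
        """On the default pooled matrix the 2-d layout fits meaningfully:
        stress well below the trivial all-at-origin solution (stress 1) and
        strictly better than the 1-d truncation."""
        mat = cc.derive_indicators(complete_cohort)
        filtered, _ = cc.exclusion_filter(mat)
        imps = cc.impute(filtered, m_count=2, seed=2)
        net = cc.pooled_matrix(imps)
        rho = np.nan_to_num(net.rho, nan=0.0)
        s2 = kruskal_stress(rho, net.layout)
        s1 = kruskal_stress(rho, np.column_stack([net.layout[:, 0], np.zeros(13)]))
        assert s2 < 0.6
        assert s2 < s1

    def test_orientation_convention(self):
        rho = np.eye(4)
        rho[0, 1] = rho[1, 0] = 0.5
        coords = cc.mds_layout(rho)
        assert coords[0, 0] >= 0 and coords[0, 1] >= 0


class TestEstimatorConsistency:
    def test_mean_absolute_error_small(self):
        """MAE over rho x margin grid at n=2000 stays below 0.05 (reduced
        replicate count; the full grid runs in the acceptance suite)."""
        rng = np.random.default_rng(11)
        errs = []
        for rho in (-0.5, 0.0, 0.5):
            for margin in (0.3, 0.5, 0.7):
                thr = stats.norm.ppf(margin)
                for _ in range(10):
                    z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], 2000)
                    tab = pair_table((z[:, 0] > thr).astype(int), (z[:, 1] > thr).astype(int))
                    errs.append(abs(cc.tetrachoric(tab) - rho))
        assert np.mean(errs) < 0.05
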