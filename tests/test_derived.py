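"""Finite-sample occupancy, turnover, inclusion, and surfaces."""

import numpy as np
import pytest
from scipy.special import expit

from dynocc.derived import (
    PredictionGrid,
    detection_difference,
    finite_sample_occupancy,
    inclusion_summary,
    predict_detection_surface,
    turnover_summaries,
)

from conftest import make_draws


class TestFiniteSampleOccupancy:
    def test_all_occupied(self):
        z = np.ones((50, 6, 2))
        occ = finite_sample_occupancy(make_draws(z))
        assert (occ.table["median"] == 1.0).all()
        assert (occ.table["q2.5"] == 1.0).all() and (occ.table["q97.5"] == 1.0).all()

    def test_none_occupied(self):
        occ = finite_sample_occupancy(make_draws(np.zeros((50, 6, 2))))
        assert (occ.table["mean"] == 0.0).all()

    def test_linear_mixture(self):
        # 8 sites always occupied, 6 occupied in exactly half the draws:
        # posterior mean per season = (8 + 6q)/14 with q = 0.5
        z = np.zeros((100, 14, 1), dtype=np.uint8)
        z[:, :8, 0] = 1
        z[:50, 8:, 0] = 1
        occ = finite_sample_occupancy(make_draws(z))
        assert occ.table["mean"].iloc[0] == pytest.approx((8 + 6 * 0.5) / 14)

    def test_estimate_dominates_observed(self):
        rng = np.random.default_rng(0)
        has_det = rng.random((10, 3)) < 0.4
        z = np.tile(has_det[None], (200, 1, 1)).astype(np.uint8)
        free = ~has_det
        extra = rng.random((200,) + has_det.shape) < 0.3
        z[:, free] |= extra[:, free]
        occ = finite_sample_occupancy(make_draws(z, has_detection=has_det))
        observed = occ.table["observed"].to_numpy()
        assert (occ.proportions >= observed[None, :] - 1e-12).all()


class TestTurnover:
    def test_extinction_is_complement(self):
        z = np.ones((40, 5, 3))
        draws = make_draws(z, phi=np.array([0.85, 0.85]))
        tab = turnover_summaries(draws)
        ext = tab[(tab.quantity == "extinction")]["mean"].to_numpy()
        np.testing.assert_allclose(ext, 0.15, atol=1e-12)

    def test_constant_proportion_gives_unit_growth(self):
        z = np.zeros((30, 8, 3), dtype=np.uint8)
        z[:, :4, :] = 1
        tab = turnover_summaries(make_draws(z))
        growth = tab[tab.quantity == "growth"]["mean"].to_numpy()
        np.testing.assert_allclose(growth, 1.0, atol=1e-12)

    def test_doubling_gives_lambda_two(self):
        z = np.zeros((30, 8, 2), dtype=np.uint8)
        z[:, :2, 0] = 1
        z[:, :4, 1] = 1
        tab = turnover_summaries(make_draws(z))
        assert tab[tab.quantity == "growth"]["mean"].iloc[0] == pytest.approx(2.0)

    def test_per_draw_ratio_not_ratio_of_means(self):
        # a skewed posterior: per-draw growth ratios average differently
        # from the ratio of the posterior-mean proportions (Jensen gap)
        z = np.zeros((2, 10, 2), dtype=np.uint8)
        z[0, :5, 0] = 1
        z[0, :5, 1] = 1
        z[1, :1, 0] = 1
        z[1, :9, 1] = 1
        tab = turnover_summaries(make_draws(z))
        per_draw = tab[tab.quantity == "growth"]["mean"].iloc[0]
        ratio_of_means = ((0.5 + 0.9) / 2) / ((0.5 + 0.1) / 2)
        assert per_draw == pytest.approx((1.0 + 9.0) / 2)
        assert abs(per_draw - ratio_of_means) > 0.5

    def test_zero_denominator_draws_dropped(self):
        z = np.zeros((4, 6, 2), dtype=np.uint8)
        z[0] = 1  # one draw fully occupied, three empty in season 1
        z[1:, :, 1] = 1
        tab = turnover_summaries(make_draws(z))
        growth = tab[tab.quantity == "growth"]
        assert growth["n_dropped"].iloc[0] == 3

    def test_all_zero_denominator_errors(self):
        z = np.zeros((5, 4, 2), dtype=np.uint8)
        z[:, :, 1] = 1
        with pytest.raises(ValueError, match="undefined"):
            turnover_summaries(make_draws(z))


class TestInclusionSummary:
    def test_mean_and_keep(self):
        z = np.zeros((4, 3, 2))
        w = np.ones((4, 4))
        w[2, 1] = 0  # current excluded in one of four draws
        draws = make_draws(z, w_alpha=w[None][0])
        draws.w_alpha = w[None].astype(np.int8)
        tab = inclusion_summary(draws).set_index("parameter")
        assert tab.loc["current", "inclusion_mean"] == pytest.approx(0.75)
        assert bool(tab.loc["current", "keep"])

    def test_boundary_is_dropped(self):
        z = np.zeros((4, 3, 2))
        w = np.ones((4, 4))
        w[:2, 1] = 0  # exactly half the draws
        draws = make_draws(z)
        draws.w_alpha = w[None].astype(np.int8)
        tab = inclusion_summary(draws).set_index("parameter")
        assert tab.loc["current", "inclusion_mean"] == 0.5
        assert not bool(tab.loc["current", "keep"])

    def test_product_rule_interaction(self):
        z = np.zeros((4, 3, 2))
        w = np.ones((4, 4))
        w[:, 1] = 0  # current never in -> effective interaction never in
        draws = make_draws(z)
        draws.w_alpha = w[None].astype(np.int8)
        tab = inclusion_summary(draws).set_index("parameter")
        assert tab.loc["current_none", "inclusion_mean"] == 0.0


def _grid(n_cells=6, bottom="canopy"):
    times = np.array([0.0, 1200.0])
    return PredictionGrid(
        cell_id=np.arange(n_cells), x=np.arange(n_cells, dtype=float),
        y=np.zeros(n_cells), depth=np.full(n_cells, -20.0),
        bottom_type=np.array([bottom] * n_cells), times=times,
        current=np.full((n_cells, 2), 0.11))


class TestSurfaces:
    def test_all_canopy_at_mean_current(self):
        rng = np.random.default_rng(1)
        alpha = np.column_stack([rng.normal(size=40), rng.normal(size=40),
                                 rng.normal(size=40), rng.normal(size=40)])
        z = np.zeros((40, 3, 2))
        draws = make_draws(z, constants={"current": (0.11, 0.05),
                                         "effort": (60.0, 10.0)})
        draws.alpha = alpha[None]
        surf = predict_detection_surface(draws, _grid())
        expected = expit(alpha[:, 0]).mean()
        np.testing.assert_allclose(surf["p_mean"], expected, atol=1e-12)

    def test_cell_order_invariance(self):
        rng = np.random.default_rng(2)
        draws = make_draws(np.zeros((30, 3, 2)),
                           constants={"current": (0.11, 0.05)})
        draws.alpha = rng.normal(size=(1, 30, 4))
        grid = _grid(5)
        grid.current = rng.uniform(0.01, 0.3, size=(5, 2))
        grid.bottom_type = np.array(["canopy", "none", "none", "canopy", "none"])
        perm = np.array([3, 0, 4, 1, 2])
        grid2 = PredictionGrid(cell_id=grid.cell_id[perm], x=grid.x[perm],
                               y=grid.y[perm], depth=grid.depth[perm],
                               bottom_type=grid.bottom_type[perm],
                               times=grid.times, current=grid.current[perm])
        a = predict_detection_surface(draws, grid).set_index(["cell_id", "time"])
        b = predict_detection_surface(draws, grid2).set_index(["cell_id", "time"])
        np.testing.assert_allclose(a.loc[b.index, "p_mean"], b["p_mean"],
                                   atol=1e-12)

    def test_missing_constants_error(self):
        draws = make_draws(np.zeros((30, 3, 2)), constants={})
        draws.standardization_constants = {}
        with pytest.raises(ValueError, match="standardization"):
            predict_detection_surface(draws, _grid())


class TestDetectionDifference:
    def test_no_bottom_type_effect(self):
        draws = make_draws(np.zeros((25, 3, 2)),
                           alpha=np.array([-0.5, 0.8, 0.0, 0.0]),
                           constants={"current": (0.11, 0.05)})
        tab = detection_difference(draws, np.linspace(0.01, 0.31, 7))
        np.testing.assert_allclose(tab["mean"], 0.0, atol=1e-12)
        assert not tab["excludes_zero"].any()

    def test_summarize_after_subtraction(self):
        rng = np.random.default_rng(3)
        draws = make_draws(np.zeros((200, 3, 2)),
                           constants={"current": (0.11, 0.05)})
        draws.alpha = rng.normal(size=(1, 200, 4))
        currents = np.array([0.05, 0.25])
        tab = detection_difference(draws, currents)
        from dynocc.derived import _det_coefficients, _p_draws
        from dynocc.model_core import apply_standardization
        coef = _det_coefficients(draws, "draws")
        c = apply_standardization(currents, "current",
                                  draws.standardization_constants)
        diff = (_p_draws(coef, c, np.ones(2)) - _p_draws(coef, c, np.zeros(2)))
        np.testing.assert_allclose(tab["mean"], diff.mean(axis=0), atol=1e-12)
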