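"""Morris screening: design construction, elementary effects, RMS
objective and threshold selection."""

import numpy as np
import pytest

from hibrain.errors import ConfigError
from hibrain.observables import SignalSet
from hibrain.sensitivity import (build_design, elementary_effects,
                                 rms_objective, screen)


def _ranges(k):
    return {f"p{i}": (0.0, 1.0) for i in range(k)}


class TestDesign:
    def test_size_is_r_times_k_plus_1(self):
        d = build_design(_ranges(2), r=1, seed=0)
        assert d.n_points == 3
        d = build_design(_ranges(5), r=7, seed=0)
        assert d.n_points == 7 * 6

    def test_each_trajectory_changes_every_parameter_once(self):
        d = build_design(_ranges(4), r=6, seed=3)
        for traj in range(6):
            block = d.changed[traj * 5:(traj + 1) * 5]
            assert block[0] == -1
            assert sorted(block[1:]) == [0, 1, 2, 3]

    def test_points_lie_on_level_grid(self):
        # brute-force grid membership on a small design
        levels = 4
        d = build_design(_ranges(3), r=5, levels=levels, seed=1)
        grid = np.arange(levels) / (levels - 1)
        for x in d.points.ravel():
            assert np.min(np.abs(grid - x)) < 1e-12

    def test_seed_reproducibility(self):
        a = build_design(_ranges(6), r=4, seed=42)
        b = build_design(_ranges(6), r=4, seed=42)
        c = build_design(_ranges(6), r=4, seed=43)
        assert np.array_equal(a.points, b.points)
        assert not np.array_equal(a.points, c.points)

    def test_degenerate_range_rejected(self):
        with pytest.raises(ConfigError):
            build_design({"a": (1.0, 1.0)}, r=2)

    def test_physical_units_respected(self):
        d = build_design({"a": (2.0, 4.0), "b": (-1.0, 1.0)}, r=3, seed=0)
        assert d.points[:, 0].min() >= 2.0 and d.points[:, 0].max() <= 4.0
        assert d.points[:, 1].min() >= -1.0 and d.points[:, 1].max() <= 1.0


class TestElementaryEffects:
    def test_linear_function_recovers_coefficients(self):
        """On f = sum a_i x_i the mu* are proportional to |a_i| and the
        effects have zero spread."""
        coeffs = np.array([3.0, -1.5, 0.5, 0.0])
        d = build_design(_ranges(4), r=20, seed=7)
        y = d.points @ coeffs
        res = elementary_effects(d, y)
        mu = res.mu_star["output"].to_numpy()
        assert mu == pytest.approx(np.abs(coeffs), rel=1e-9, abs=1e-9)
        assert res.sigma["output"].to_numpy()[:3] == \
            pytest.approx(np.zeros(3), abs=1e-9)
        # normalisation: the largest coefficient maps to exactly 1
        norm = res.mu_star_normalised["output"].to_numpy()
        assert norm[0] == pytest.approx(1.0)

    def test_interaction_shows_in_sigma(self):
        d = build_design(_ranges(2), r=30, seed=11)
        y = d.points[:, 0] * d.points[:, 1]
        res = elementary_effects(d, y)
        assert (res.sigma["output"] > 0.01).all()

    def test_inert_parameter_has_zero_mu(self):
        d = build_design(_ranges(3), r=10, seed=2)
        y = d.points[:, 0] ** 2
        res = elementary_effects(d, y)
        assert res.mu_star.loc["p2", "output"] == pytest.approx(0.0)

    def test_failed_points_invalidate_only_their_steps(self):
        d = build_design(_ranges(2), r=10, seed=5)
        y = (d.points @ np.array([1.0, 2.0])).astype(float)
        y[4] = np.nan  # one failed simulation
        res = elementary_effects(d, y)
        assert res.counts["output"].sum() < 2 * 10
        assert np.isfinite(res.mu_star["output"]).all()

    def test_all_failed_marks_missing(self):
        d = build_design(_ranges(2), r=3, seed=5)
        y = np.full(d.n_points, np.nan)
        res = elementary_effects(d, y)
        assert res.mu_star["output"].isna().all()


class TestRMSObjective:
    def _sig(self, t, v):
        return SignalSet(time=np.asarray(t, float),
                         data={"pH": np.asarray(v, float)})

    def test_identical_signals_zero(self):
        s = self._sig([0, 60, 120], [7.0, 6.8, 6.9])
        assert rms_objective(s, s, "pH") == 0.0

    def test_constant_offset(self):
        a = self._sig([0, 60, 120], [7.0, 6.8, 6.9])
        b = self._sig([0, 60, 120], [7.1, 6.9, 7.0])
        assert rms_objective(a, b, "pH") == pytest.approx(0.1)

    def test_hand_computed_example(self):
        a = self._sig([0, 1, 2], [1.0, 2.0, 3.0])
        b = self._sig([0, 1, 2], [1.0, 0.0, 0.0])
        assert rms_objective(a, b, "pH") == \
            pytest.approx(np.sqrt((0 + 4 + 9) / 3))

    def test_interpolation_onto_measurement_grid(self):
        a = self._sig([0, 2], [0.0, 2.0])       # modelled, coarse
        b = self._sig([0, 1, 2], [0.0, 1.0, 2.0])  # measured
        assert rms_objective(a, b, "pH") == pytest.approx(0.0, abs=1e-14)

    def test_window_restriction(self):
        a = self._sig([0, 1, 2, 3], [0.0, 0.0, 5.0, 5.0])
        b = self._sig([0, 1, 2, 3], [0.0, 0.0, 0.0, 0.0])
        assert rms_objective(a, b, "pH", t_window=(0, 1)) == 0.0

    def test_empty_overlap_rejected(self):
        a = self._sig([0, 1], [0.0, 0.0])
        b = self._sig([5, 6], [0.0, 0.0])
        with pytest.raises(ConfigError):
            rms_objective(a, b, "pH")


class TestScreening:
    def _result(self, mu):
        d = build_design(_ranges(len(mu)), r=2, seed=0)
        y = d.points @ np.asarray(mu, float)
        return elementary_effects(d, y)

    def test_threshold_selects_influential(self):
        res = self._result([10.0, 6.0, 1.0])
        groups = screen(res, threshold=0.5)
        assert groups["output"] == ["p0", "p1"]

    def test_zero_threshold_selects_all(self):
        res = self._result([10.0, 6.0, 1.0])
        assert len(screen(res, threshold=0.0)["output"]) == 3

    def test_averaging_across_datasets(self):
        a = self._result([10.0, 2.0, 1.0])
        b = self._result([2.0, 10.0, 1.0])
        groups = screen([a, b], threshold=0.5)
        assert set(groups["output"]) == {"p0", "p1"}

    def test_invariant_to_output_rescaling(self):
        d = build_design(_ranges(3), r=5, seed=9)
        y = d.points @ np.array([4.0, 2.0, 0.5])
        g1 = screen(elementary_effects(d, y), threshold=0.5)
        g2 = screen(elementary_effects(d, 1000.0 * y), threshold=0.5)
        assert g1 == g2
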