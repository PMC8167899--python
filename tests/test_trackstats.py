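"""Velocity, persistence, coordination, and group comparisons."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metquant.trackstats import (
    compare_groups,
    coordination,
    directional_persistence,
    embryo_summary,
    instantaneous_speeds,
    significance_stars,
    track_metrics,
    track_velocity,
)

from conftest import make_track

# Reference values computed independently with R 4.3 (t.test with
# var.equal=TRUE / FALSE, anova(lm(...))) on the fixture vectors below.
FIX_A = [1.20, 1.05, 1.31, 1.18, 0.98, 1.22]
FIX_B = [0.85, 0.90, 1.02, 0.77, 0.96, 0.88]
FIX_C = [0.75, 0.80, 0.92, 0.67, 0.86, 0.78]
R_T_EQUALVAR = 4.2885635717649
R_P_EQUALVAR = 0.00158980054401583
R_P_WELCH = 0.00197641435393681
R_F_ANOVA = 21.0
R_P_ANOVA = 4.48356040690602e-05
R_MEAN_A = 1.15666666666667
R_SEM_A = 0.0491709037722287


def _straight_track(step, n=10, start=(5.0, 5.0, 5.0)):
    pos = np.array(start) + np.outer(np.arange(n), step)
    return make_track(pos)


class TestSpeedsAndVelocity:
    def test_constant_displacement_gives_constant_speed(self):
        tr = _straight_track([0, 0, 2.4], n=8)
        speeds = instantaneous_speeds(tr, 2.0)
        assert np.allclose(speeds, 1.2)
        assert track_velocity(tr, 2.0) == pytest.approx(1.2)

    def test_stationary_track_zero(self):
        tr = _straight_track([0, 0, 0], n=5)
        assert np.allclose(instantaneous_speeds(tr, 2.0), 0.0)

    def test_doubling_interval_halves_speed(self):
        tr = _straight_track([0, 1.0, 1.0], n=6)
        assert np.allclose(
            instantaneous_speeds(tr, 4.0), instantaneous_speeds(tr, 2.0) / 2.0
        )

    def test_mixed_speeds_average(self):
        pos = [[0, 0, 0], [0, 0, 0], [0, 0, 2.4]]
        assert track_velocity(make_track(pos), 2.0) == pytest.approx(0.6)

    def test_short_track_raises(self):
        with pytest.raises(ValueError):
            instantaneous_speeds(make_track([[0, 0, 0]]), 2.0)


class TestPersistence:
    def test_straight_line_is_one(self):
        assert directional_persistence(_straight_track([0, 1, 2])) == pytest.approx(1.0)

    def test_out_and_back_is_zero(self):
        pos = [[0, 0, 0], [0, 0, 3], [0, 0, 0]]
        assert directional_persistence(make_track(pos)) == pytest.approx(0.0)

    def test_right_angle_is_sqrt2_over_2(self):
        pos = [[0, 0, 0], [0, 0, 2], [0, 2, 2]]
        assert directional_persistence(make_track(pos)) == pytest.approx(
            np.sqrt(2) / 2
        )

    def test_zero_path_flagged(self):
        with pytest.warns(UserWarning, match="zero path"):
            value = directional_persistence(make_track([[1, 1, 1], [1, 1, 1]]))
        assert np.isnan(value)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(seed=st.integers(0, 1000))
    def test_bounded_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        pos = np.cumsum(rng.normal(0, 1, (8, 3)), axis=0)
        p = directional_persistence(make_track(pos))
        assert 0.0 <= p <= 1.0 + 1e-12


class TestCoordination:
    def test_identical_parallel_tracks(self):
        rng = np.random.default_rng(0)
        steps = rng.normal(0.5, 0.3, (9, 3))
        pos = np.vstack([[0, 0, 0], np.cumsum(steps, axis=0)])
        t1 = make_track(pos, track_id=0)
        t2 = make_track(pos + [0, 2, 0], track_id=1)
        out = coordination([t1, t2], 2.0)
        assert np.allclose(out["coordination"], 1.0)

    def test_opposed_tracks(self):
        rng = np.random.default_rng(1)
        steps = rng.normal(0.5, 0.3, (9, 3))
        pos1 = np.vstack([[0, 0, 0], np.cumsum(steps, axis=0)])
        pos2 = np.vstack([[0, 2, 0], [0, 2, 0] - np.cumsum(steps, axis=0)])
        out = coordination(
            [make_track(pos1, 0), make_track(pos2, 1)], 2.0
        )
        assert np.allclose(out["coordination"], -1.0)

    def test_independent_random_walks_near_zero(self):
        """Null case: 30 independent random walks give mean coordination
        within ±0.1 of zero."""
        rng = np.random.default_rng(2)
        tracks = []
        for i in range(30):
            start = rng.uniform(0, 50, 3)
            pos = start + np.vstack(
                [[0, 0, 0], np.cumsum(rng.normal(0, 1, (29, 3)), axis=0)]
            )
            tracks.append(make_track(pos, track_id=i))
        out = coordination(tracks, 2.0)
        assert abs(out["coordination"].mean()) <= 0.1

    def test_frame_offset_invariance(self):
        """Adding a constant offset to all positions changes nothing;
        identical tracks stay at coordination 1 under a shared constant
        velocity."""
        rng = np.random.default_rng(3)
        steps = rng.normal(0.2, 0.4, (9, 3))
        pos = np.vstack([[0, 0, 0], np.cumsum(steps, axis=0)])
        t = [make_track(pos, 0), make_track(pos + [1, 1, 1], 1)]
        base = coordination(t, 2.0)["coordination"].to_numpy()
        shifted = [
            make_track(pos + 100.0, 0),
            make_track(pos + 100.0 + [1, 1, 1], 1),
        ]
        assert np.allclose(
            coordination(shifted, 2.0)["coordination"].to_numpy(), base
        )
        drifted_pos = pos + np.outer(np.arange(10), [0.3, 0.3, 0.3])
        drifted = [make_track(drifted_pos, 0), make_track(drifted_pos + [0, 1, 0], 1)]
        assert np.allclose(coordination(drifted, 2.0)["coordination"], 1.0)

    def test_zero_variance_flagged(self):
        t1 = make_track(np.tile([0.0, 0.0, 0.0], (5, 1)), 0)
        t2 = make_track(np.cumsum(np.ones((5, 3)), axis=0), 1)
        with pytest.warns(UserWarning, match="zero-variance"):
            out = coordination([t1, t2], 2.0)
        assert np.isnan(out.loc[out.track_id == 0, "coordination"]).all()

    def test_cosine_mode_directed(self):
        t1 = _straight_track([0, 0, 1])
        t2 = make_track(
            np.array([5.0, 7.0, 5.0]) + np.outer(np.arange(10), [0, 0, -1]), 1
        )
        out = coordination([t1, t2], 2.0, mode="cosine")
        assert np.allclose(out["coordination"], -1.0)


class TestEmbryoSummary:
    def _metrics(self, velocities, cell_type="PMEC"):
        return pd.DataFrame(
            {
                "track_id": range(len(velocities)),
                "cell_type": cell_type,
                "velocity_um_per_min": velocities,
                "directional_persistence": 0.9,
                "coordination": 0.8,
            }
        )

    def test_uniform_velocity(self):
        with pytest.warns(UserWarning):
            out = embryo_summary(self._metrics([1.2] * 5), "e1")
        assert out["velocity_um_per_min"].iloc[0] == pytest.approx(1.2)

    def test_simple_mean(self):
        with pytest.warns(UserWarning):
            out = embryo_summary(self._metrics([1.0, 2.0, 3.0]), "e1")
        assert out["velocity_um_per_min"].iloc[0] == pytest.approx(2.0)

    def test_nan_values_skipped_not_zeroed(self):
        m = self._metrics([1.0, 2.0, 3.0])
        m.loc[1, "coordination"] = np.nan
        with pytest.warns(UserWarning):
            out = embryo_summary(m, "e1")
        assert out["coordination"].iloc[0] == pytest.approx(0.8)

    def test_no_tracks_raises(self):
        with pytest.raises(ValueError):
            embryo_summary(pd.DataFrame(), "e1")


class TestCompareGroups:
    def _table(self, values):
        return pd.DataFrame(
            {
                "embryo_id": range(len(values)),
                "velocity_um_per_min": values,
                "directional_persistence": values,
                "coordination": values,
            }
        )

    def test_identical_samples_t0_p1(self):
        data = {"a": self._table([1.0, 2.0, 3.0]), "b": self._table([1.0, 2.0, 3.0])}
        out = compare_groups(data, control="a")
        row = out.pairwise.iloc[0]
        assert row["t"] == pytest.approx(0.0)
        assert row["p"] == pytest.approx(1.0)
        assert row["stars"] == ""

    def test_forced_separation_three_stars(self):
        rng = np.random.default_rng(0)
        data = {
            "a": self._table(rng.normal(0, 1e-3, 4)),
            "b": self._table(10 + rng.normal(0, 1e-3, 4)),
        }
        out = compare_groups(data, control="a")
        assert (out.pairwise["p"] < 1e-3).all()
        assert (out.pairwise["stars"] == "***").all()

    def test_matches_independent_reference_to_1e10(self):
        """t, F, p, mean, and SEM agree with R to 1e-10 on fixed fixtures."""
        data = {
            "wt": self._table(FIX_A),
            "mut1": self._table(FIX_B),
            "mut2": self._table(FIX_C),
        }
        out = compare_groups(data, control="wt")
        row = out.pairwise[
            (out.pairwise.condition == "mut1")
            & (out.pairwise.metric == "velocity_um_per_min")
        ].iloc[0]
        assert row["t"] == pytest.approx(-R_T_EQUALVAR, abs=1e-10)
        assert row["p"] == pytest.approx(R_P_EQUALVAR, abs=1e-10)
        anova = out.anova[out.anova.metric == "velocity_um_per_min"].iloc[0]
        assert anova["F"] == pytest.approx(R_F_ANOVA, abs=1e-10)
        assert anova["p"] == pytest.approx(R_P_ANOVA, abs=1e-10)
        mean_row = out.means[
            (out.means.condition == "wt")
            & (out.means.metric == "velocity_um_per_min")
        ].iloc[0]
        assert mean_row["mean"] == pytest.approx(R_MEAN_A, abs=1e-10)
        assert mean_row["sem"] == pytest.approx(R_SEM_A, abs=1e-10)

    def test_welch_variant_matches_reference(self):
        data = {"wt": self._table(FIX_A), "mut": self._table(FIX_B)}
        out = compare_groups(data, control="wt", equal_var=False)
        assert out.pairwise.iloc[0]["p"] == pytest.approx(R_P_WELCH, abs=1e-10)

    def test_single_embryo_condition_raises(self):
        data = {"a": self._table([1.0, 2.0]), "b": self._table([1.0])}
        with pytest.raises(ValueError, match="fewer than 2"):
            compare_groups(data, control="a")


class TestStars:
    @pytest.mark.parametrize(
        "p, stars",
        [
            (0.049, "*"), (0.051, ""), (0.05, "*"),
            (0.01, "**"), (0.009, "**"), (0.001, "***"), (0.0001, "***"),
        ],
    )
    def test_thresholds(self, p, stars):
        assert significance_stars(p) == stars


def test_track_metrics_table_shape():
    rng = np.random.default_rng(5)
    tracks = []
    for i in range(4):
        pos = rng.uniform(0, 20, 3) + np.cumsum(rng.normal(0.3, 0.2, (6, 3)), axis=0)
        tracks.append(make_track(pos, track_id=i, diameter_um=3.0))
    out = track_metrics(tracks, 2.0)
    assert len(out) == 4
    assert set(out.columns) >= {
        "track_id", "cell_type", "velocity_um_per_min",
        "directional_persistence", "coordination", "partner_track_id",
    }
    assert out["coordination"].between(-1, 1).all()
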