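"""Group velocity: pair formula, windows, linking, frame-geometry invariances."""

import math

import numpy as np
import pandas as pd
import pytest

from recumbency.velocity import (
    Animal,
    TrackedFrame,
    frames_from_dataframe,
    link,
    pair_velocity,
    stream_velocities,
    window_summarize,
)


def frame(t, positions, standing=None, pen="pen01"):
    standing = standing or [True] * len(positions)
    return TrackedFrame(
        pen_id=pen,
        t_s=t,
        animals=tuple(
            Animal(i, x, y, s) for i, ((x, y), s) in enumerate(zip(positions, standing))
        ),
    )


class TestPairVelocity:
    def test_identical_frames_give_zero(self):
        f0 = frame(0.0, [(0.1, 0.2), (1.0, 1.5)])
        f1 = frame(1.0, [(0.1, 0.2), (1.0, 1.5)])
        assert pair_velocity(f0, f1) == 0.0

    def test_three_four_five_triangle(self):
        # one standing animal moves 0.3 m east and 0.4 m north in 1 s
        f0 = frame(0.0, [(0.0, 0.0), (1.0, 1.0)], standing=[True, False])
        f1 = frame(1.0, [(0.3, 0.4), (1.2, 1.2)], standing=[True, False])
        assert pair_velocity(f0, f1) == pytest.approx(0.5)

    def test_matches_hand_summed_standing_displacements(self, rng):
        p0 = rng.uniform(0, 2.5, size=(5, 2))
        p1 = p0 + rng.normal(0, 0.05, size=(5, 2))
        standing = [True, True, False, False, False]
        f0 = frame(0.0, p0.tolist(), standing=standing)
        f1 = frame(2.0, p1.tolist(), standing=standing)
        expected = sum(
            math.hypot(*(p1[i] - p0[i])) for i in range(5) if standing[i]
        ) / 2.0
        assert pair_velocity(f0, f1) == pytest.approx(expected)

    def test_no_standing_animals_means_zero(self, rng):
        p0 = rng.uniform(0, 2, size=(4, 2))
        p1 = rng.uniform(0, 2, size=(4, 2))
        f0 = frame(0.0, p0.tolist(), standing=[False] * 4)
        f1 = frame(1.0, p1.tolist(), standing=[False] * 4)
        assert pair_velocity(f0, f1) == 0.0

    def test_standing_flag_comes_from_later_frame(self):
        f0 = frame(0.0, [(0.0, 0.0)], standing=[False])
        f1 = frame(1.0, [(1.0, 0.0)], standing=[True])
        assert pair_velocity(f0, f1) == pytest.approx(1.0)
        f1b = frame(1.0, [(1.0, 0.0)], standing=[False])
        f0b = frame(0.0, [(0.0, 0.0)], standing=[True])
        assert pair_velocity(f0b, f1b) == 0.0

    def test_rejects_bad_pairs(self):
        f0 = frame(0.0, [(0, 0)])
        with pytest.raises(ValueError, match="time interval"):
            pair_velocity(f0, frame(0.0, [(1, 1)]))
        with pytest.raises(ValueError, match="different pens"):
            pair_velocity(f0, frame(1.0, [(1, 1)], pen="other"))
        with pytest.raises(ValueError, match="empty"):
            pair_velocity(f0, TrackedFrame("pen01", 1.0, ()))

    def test_translation_and_rotation_invariance(self, rng):
        p0 = rng.uniform(0, 2, size=(6, 2))
        p1 = p0 + rng.normal(0, 0.1, size=(6, 2))
        base = pair_velocity(frame(0, p0.tolist()), frame(1, p1.tolist()))
        shift = np.array([0.7, -0.3])
        theta = 0.9
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        moved = pair_velocity(
            frame(0, ((p0 + shift) @ rot.T).tolist()),
            frame(1, ((p1 + shift) @ rot.T).tolist()),
        )
        assert moved == pytest.approx(base)

    def test_displacement_scaling_scales_velocity(self, rng):
        p0 = rng.uniform(0, 2, size=(4, 2))
        p1 = p0 + rng.normal(0, 0.1, size=(4, 2))
        k = 3.5
        base = pair_velocity(frame(0, p0.tolist()), frame(1, p1.tolist()))
        scaled = pair_velocity(frame(0, (k * p0).tolist()), frame(1, (k * p1).tolist()))
        assert scaled == pytest.approx(k * base)


class TestStreamVelocities:
    def test_matches_pairwise_oracle(self, rng):
        """The vectorized stream path equals explicit pair_velocity calls."""
        rows = []
        for t in range(20):
            for a in range(3):
                rows.append(
                    {
                        "pen_id": "p",
                        "t_s": float(t),
                        "animal_id": a,
                        "x_m": rng.uniform(0, 2.5),
                        "y_m": rng.uniform(0, 3.2),
                        "detected_standing": int(rng.random() < 0.5),
                    }
                )
        df = pd.DataFrame(rows)
        fast = stream_velocities(df)
        frames = frames_from_dataframe(df)
        slow = [pair_velocity(a, b) for a, b in zip(frames, frames[1:])]
        np.testing.assert_allclose(fast["v_mps"].to_numpy(), slow)

    def test_absent_animal_contributes_zero(self):
        df = pd.DataFrame(
            {
                "pen_id": "p",
                "t_s": [0.0, 0.0, 1.0],
                "animal_id": [0, 1, 0],
                "x_m": [0.0, 5.0, 1.0],
                "y_m": [0.0, 5.0, 0.0],
                "detected_standing": [1, 1, 1],
            }
        )
        out = stream_velocities(df)
        assert out["v_mps"].tolist() == [1.0]  # animal 1 absent at t=1 contributes 0


class TestWindows:
    def make_vels(self, times, values, pen="p"):
        return pd.DataFrame({"pen_id": pen, "t_s": times, "v_mps": values})

    def test_constant_velocity_window_mean(self):
        v = self.make_vels(np.arange(0.0, 300.0), np.full(300, 0.42))
        out = window_summarize(v, 300.0, origin=0.0)
        assert out.loc[0, "v_mps"] == pytest.approx(0.42)
        assert out.loc[0, "n_frame_pairs"] == 300

    def test_two_point_window_mean(self):
        v = self.make_vels([10.0, 20.0], [0.1, 0.3])
        out = window_summarize(v, 300.0, origin=0.0)
        assert out.loc[0, "v_mps"] == pytest.approx(0.2)

    def test_seeded_stream_equals_independent_mean(self, rng):
        times = np.arange(1.0, 301.0)
        vals = rng.exponential(0.001, size=300)
        out = window_summarize(self.make_vels(times, vals), 300.0, origin=0.0)
        # independent second path: plain python accumulation
        by_window = {}
        for t, v in zip(times, vals):
            by_window.setdefault(int(t // 300), []).append(v)
        for w, grp in by_window.items():
            assert out.loc[w, "v_mps"] == pytest.approx(sum(grp) / len(grp))

    def test_empty_windows_are_flagged_missing(self):
        v = self.make_vels([10.0, 910.0], [0.1, 0.2])
        out = window_summarize(v, 300.0, origin=0.0)
        assert out.loc[1, "n_frame_pairs"] == 0
        assert math.isnan(out.loc[1, "v_mps"])

    def test_time_shift_leaves_summaries_unchanged(self, rng):
        times = np.sort(rng.uniform(0, 1200, 100))
        vals = rng.exponential(0.001, 100)
        a = window_summarize(self.make_vels(times, vals), 300.0, origin=0.0)
        b = window_summarize(self.make_vels(times + 5000.0, vals), 300.0, origin=5000.0)
        np.testing.assert_allclose(a["v_mps"], b["v_mps"])
        assert a["n_frame_pairs"].tolist() == b["n_frame_pairs"].tolist()


class TestLink:
    def windows(self):
        return pd.DataFrame(
            {
                "pen_id": ["p", "p", "p"],
                "window_start_s": [300.0, 600.0, 900.0],
                "window_end_s": [600.0, 900.0, 1200.0],
                "v_mps": [0.01, 0.002, math.nan],
                "n_frame_pairs": [10, 10, 0],
            }
        )

    def test_containment_match(self):
        labels = pd.DataFrame({"pen_id": ["p"], "t_s": [610.0], "code": [0]})
        linked, dropped = link(self.windows(), labels)
        assert dropped == 0
        assert linked.loc[0, "v_mps"] == pytest.approx(0.002)

    def test_uncovered_or_empty_windows_drop_labels(self):
        labels = pd.DataFrame(
            {"pen_id": ["p", "p", "p"], "t_s": [100.0, 950.0, 400.0], "code": [0, 1, 1]}
        )
        linked, dropped = link(self.windows(), labels)
        assert dropped == 2  # before first window; inside the empty window
        assert len(linked) == 1

    def test_duplicate_labels_rejected(self):
        labels = pd.DataFrame({"pen_id": ["p", "p"], "t_s": [610.0, 610.0], "code": [0, 1]})
        with pytest.raises(ValueError, match="duplicate"):
            link(self.windows(), labels)

    def test_bulk_join_verified_by_scan(self, rng):
        """Every linked sample's velocity equals its covering window's."""
        n_windows = 400
        windows = pd.DataFrame(
            {
                "pen_id": "p",
                "window_start_s": 300.0 * np.arange(n_windows),
                "window_end_s": 300.0 * (np.arange(n_windows) + 1),
                "v_mps": rng.exponential(0.001, n_windows),
                "n_frame_pairs": 5,
            }
        )
        t = np.sort(rng.choice(np.arange(0, n_windows * 300), size=1023, replace=False)).astype(float)
        labels = pd.DataFrame({"pen_id": "p", "t_s": t, "code": rng.integers(0, 2, 1023)})
        linked, dropped = link(windows, labels)
        assert dropped == 0 and len(linked) == 1023
        for row in linked.itertuples(index=False):
            w = windows[
                (windows.window_start_s <= row.t_s) & (row.t_s < windows.window_end_s)
            ].iloc[0]
            assert row.v_mps == w.v_mps
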