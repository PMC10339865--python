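"""Cumulative group velocity from tracked frames, 5-minute windows, linking.

The activity signal is the cumulative group velocity v = dp/dt: for each
pair of consecutive frames, the Euclidean displacements of all animals
detected as standing are summed and divided by the frame time interval.
Per-pair velocities are then averaged over 5-minute windows, and each
human-coded image is joined to the window containing its timestamp by pen
and time.

Conventions (fixed, testable choices where the measurement chain leaves
room):

* the standing flag is taken from the later frame of each pair;
* animals absent from either frame of a pair contribute zero displacement
  (logged);
* windows are half-open ``[start, start + window_s)`` aligned to the
  stream's first timestamp (configurable origin), not to wall-clock marks;
* the window summary is the arithmetic mean of the per-pair velocities in
  the window; an empty window yields ``n_frame_pairs = 0`` and a missing
  (NaN) velocity.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_S = 300.0


class Animal(NamedTuple):
    animal_id: int
    x_m: float
    y_m: float
    detected_standing: bool


@dataclass(frozen=True)
class TrackedFrame:
    """Positions and detected postures of all animals in one pen frame."""

    pen_id: str
    t_s: float
    animals: tuple[Animal, ...]

    def __post_init__(self) -> None:
        ids = [a.animal_id for a in self.animals]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate animal ids in frame at t={self.t_s}")


@dataclass(frozen=True)
class VelocityRecord:
    """Summarized group velocity of one pen over one time window."""

    pen_id: str
    window_start_s: float
    window_end_s: float
    v_mps: float  # NaN when the window holds no frame pairs
    n_frame_pairs: int


@dataclass(frozen=True)
class LinkedSample:
    """A consensus-coded image joined to its window velocity."""

    pen_id: str
    t_s: float
    v_mps: float
    code: int
    blur_score: float = math.nan


def pair_velocity(prev: TrackedFrame, curr: TrackedFrame) -> float:
    """Group velocity in m/s between two consecutive frames.

    Sums the Euclidean displacement of every animal flagged as standing in
    the *current* frame, matched to the previous frame by animal id, and
    divides by the elapsed time.  Animals missing from either frame
    contribute zero.
    """
    if prev.pen_id != curr.pen_id:
        raise ValueError(f"frames from different pens: {prev.pen_id!r} vs {curr.pen_id!r}")
    dt = curr.t_s - prev.t_s
    if dt <= 0:
        raise ValueError(f"non-positive time interval {dt}")
    if not prev.animals or not curr.animals:
        raise ValueError("empty frame")
    prev_pos = {a.animal_id: (a.x_m, a.y_m) for a in prev.animals}
    dp = 0.0
    for a in curr.animals:
        if not a.detected_standing:
            continue
        if a.animal_id not in prev_pos:
            logger.info("animal %s absent from previous frame; contributes 0", a.animal_id)
            continue
        px, py = prev_pos[a.animal_id]
        dp += math.hypot(a.x_m - px, a.y_m - py)
    return dp / dt


def stream_velocities(frames: pd.DataFrame) -> pd.DataFrame:
    """Per-pair group velocities for whole tracked streams (vectorized).

    ``frames`` has columns pen_id, t_s, animal_id, x_m, y_m,
    detected_standing.  Returns one row per consecutive frame pair per pen
    with columns pen_id, t_s (timestamp of the later frame), v_mps.
    Equivalent to applying :func:`pair_velocity` to every consecutive pair.
    """
    required = {"pen_id", "t_s", "animal_id", "x_m", "y_m", "detected_standing"}
    missing = required - set(frames.columns)
    if missing:
        raise ValueError(f"frames missing columns: {sorted(missing)}")
    out = []
    for pen_id, pen in frames.groupby("pen_id", sort=True):
        times = np.sort(pen["t_s"].unique())
        if len(times) < 2:
            continue
        t_index = pd.Series(np.arange(len(times)), index=times)
        df = pen.sort_values(["animal_id", "t_s"]).copy()
        df["ti"] = t_index.loc[df["t_s"]].to_numpy()
        g = df.groupby("animal_id")
        dx = g["x_m"].diff()
        dy = g["y_m"].diff()
        consecutive = g["ti"].diff() == 1
        disp = np.hypot(dx, dy)
        valid = consecutive & (df["detected_standing"] == 1)
        disp = disp.where(valid, 0.0)
        dp = disp.groupby(df["ti"]).sum()  # indexed by later-frame index
        dp = dp.reindex(np.arange(1, len(times)), fill_value=0.0)
        dt = np.diff(times)
        out.append(
            pd.DataFrame(
                {"pen_id": pen_id, "t_s": times[1:], "v_mps": dp.to_numpy() / dt}
            )
        )
    if not out:
        return pd.DataFrame(columns=["pen_id", "t_s", "v_mps"])
    return pd.concat(out, ignore_index=True)


def window_summarize(
    velocities: pd.DataFrame,
    window_s: float = DEFAULT_WINDOW_S,
    origin: dict[str, float] | float | None = None,
) -> pd.DataFrame:
    """Average per-pair velocities over half-open windows per pen.

    ``velocities`` has columns pen_id, t_s, v_mps (per-pair values stamped
    with the later frame's time).  ``origin`` fixes the window alignment:
    a float applies to all pens, a dict maps pen_id to origin, ``None``
    aligns to each pen's first pair timestamp.  Every window between the
    origin and the last pair is emitted; empty windows carry
    ``n_frame_pairs = 0`` and NaN velocity.
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    rows = []
    for pen_id, pen in velocities.groupby("pen_id", sort=True):
        if isinstance(origin, dict):
            t0 = origin[pen_id]
        elif origin is None:
            t0 = float(pen["t_s"].min())
        else:
            t0 = float(origin)
        idx = np.floor((pen["t_s"].to_numpy() - t0) / window_s).astype(int)
        if (idx < 0).any():
            raise ValueError("velocity timestamped before the window origin")
        means = pen.groupby(idx)["v_mps"].agg(["mean", "size"])
        for w in range(int(idx.max()) + 1):
            if w in means.index:
                v, n = float(means.loc[w, "mean"]), int(means.loc[w, "size"])
            else:
                v, n = math.nan, 0
            rows.append(
                {
                    "pen_id": pen_id,
                    "window_start_s": t0 + w * window_s,
                    "window_end_s": t0 + (w + 1) * window_s,
                    "v_mps": v,
                    "n_frame_pairs": n,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["pen_id", "window_start_s", "window_end_s", "v_mps", "n_frame_pairs"],
    )


def link(
    windows: pd.DataFrame,
    labels: pd.DataFrame,
    blur_scores: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, int]:
    """Join consensus-coded images to their covering velocity window.

    ``windows`` is the output of :func:`window_summarize`; ``labels`` has
    columns pen_id, t_s, code.  Each label is matched to the window with
    ``window_start_s <= t_s < window_end_s`` in the same pen; labels with
    no covering window, or whose window holds no frame pairs, are dropped
    and counted.  ``blur_scores`` (pen_id, t_s, blur_score) is carried
    through when given.

    Returns ``(linked, n_dropped)`` where ``linked`` has columns pen_id,
    t_s, v_mps, code, blur_score.
    """
    if labels.duplicated(subset=["pen_id", "t_s"]).any():
        dups = labels[labels.duplicated(subset=["pen_id", "t_s"], keep=False)]
        raise ValueError(
            f"duplicate (pen, timestamp) labels:\n{dups[['pen_id', 't_s']]}"
        )
    rows = []
    n_dropped = 0
    win_by_pen = {p: w.reset_index(drop=True) for p, w in windows.groupby("pen_id")}
    for rec in labels.itertuples(index=False):
        pen_w = win_by_pen.get(rec.pen_id)
        match = None
        if pen_w is not None:
            hit = pen_w[
                (pen_w["window_start_s"] <= rec.t_s) & (rec.t_s < pen_w["window_end_s"])
            ]
            if len(hit):
                match = hit.iloc[0]
        if match is None or match["n_frame_pairs"] == 0 or math.isnan(match["v_mps"]):
            n_dropped += 1
            continue
        rows.append(
            {
                "pen_id": rec.pen_id,
                "t_s": rec.t_s,
                "v_mps": float(match["v_mps"]),
                "code": int(rec.code),
                "blur_score": math.nan,
            }
        )
    linked = pd.DataFrame(rows, columns=["pen_id", "t_s", "v_mps", "code", "blur_score"])
    if blur_scores is not None and len(linked):
        linked = linked.drop(columns="blur_score").merge(
            blur_scores[["pen_id", "t_s", "blur_score"]],
            on=["pen_id", "t_s"],
            how="left",
        )
    if n_dropped:
        logger.info("link: %d labels dropped (no covering non-empty window)", n_dropped)
    return linked, n_dropped


def frames_from_dataframe(df: pd.DataFrame) -> list[TrackedFrame]:
    """Materialize :class:`TrackedFrame` objects from a long-format table."""
    frames = []
    for (pen_id, t_s), grp in df.groupby(["pen_id", "t_s"], sort=True):
        animals = tuple(
            Animal(int(a.animal_id), float(a.x_m), float(a.y_m), bool(a.detected_standing))
            for a in grp.itertuples(index=False)
        )
        frames.append(TrackedFrame(pen_id=pen_id, t_s=float(t_s), animals=animals))
    return frames
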