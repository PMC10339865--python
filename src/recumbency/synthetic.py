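"""Synthetic pen trajectories, ethograms and images for the recumbency pipeline.

The real input to the analysis is the output of a camera tracker: per-frame
positions and detected postures of ~18 weaned pigs in a 2.55 m x 3.20 m pen,
plus frames sampled every 20 minutes for human coding.  This module emulates
that output with a controllable group-level behavior model so every
downstream stage (velocity aggregation, blur QC, coding, threshold fitting,
cross-validation) can be exercised and tested without farm data.

Behavior is generated at the group level, because the unit of analysis is
the group code: a state schedule alternates between ``all_recumbent``
(every animal only jitters by tracker detection noise, and is flagged
standing only at a small false-detection rate) and ``some_active`` (a fixed
number of animals move with speeds drawn from an activity distribution and
are flagged standing).  The ground-truth ethogram codes each 20-minute
sampling instant 1 if the generating state has at least one non-recumbent
animal, else 0.

Default magnitudes are set to the scale of the real system: recumbent
detection jitter of a few tenths of a millimetre per second so that the
recumbent-class velocity distribution sits near the observed decision
boundary of ~6e-4 m/s, and active speeds of a few millimetres per second
of cumulative group velocity, giving the clearly bimodal velocity histogram
the threshold method presumes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.stats import norm

from .blur import ImageRecord

logger = logging.getLogger(__name__)

ALL_RECUMBENT = "all_recumbent"
SOME_ACTIVE = "some_active"

#: Default RNG seed used across the package for reproducibility.
DEFAULT_SEED = 123


@dataclass(frozen=True)
class GaussianSpec:
    """A (mean, sd) speed distribution in m/s; draws are clipped at 0."""

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be nonnegative")

    def sample(self, rng: np.random.Generator, size) -> np.ndarray:
        return np.clip(rng.normal(self.mean, self.sd, size=size), 0.0, None)


@dataclass(frozen=True)
class PenConfig:
    """Geometry and sampling setup of one rearing pen."""

    pen_id: str
    width_m: float = 2.55
    height_m: float = 3.20
    n_animals: int = 18
    frame_interval_s: float = 1.0
    #: Interval at which single frames are extracted for coding (20 min).
    sampling_interval_s: float = 1200.0

    def __post_init__(self) -> None:
        if self.width_m <= 0 or self.height_m <= 0:
            raise ValueError("pen dimensions must be positive")
        if self.n_animals < 1:
            raise ValueError("need at least one animal")
        if self.frame_interval_s <= 0 or self.sampling_interval_s <= 0:
            raise ValueError("intervals must be positive")


@dataclass(frozen=True)
class BehaviorScenario:
    """Group-level behavior schedule plus movement/noise distributions.

    ``state_schedule`` is a sequence of ``(start_time_s, state)`` pairs with
    strictly increasing start times, the first at 0.  Each state holds until
    the next start (or the end of ``duration_s``).
    """

    duration_s: float
    state_schedule: tuple[tuple[float, str], ...]
    n_active_when_active: int = 1
    active_speed_dist: GaussianSpec = GaussianSpec(5e-3, 1.2e-3)
    recumbent_jitter_dist: GaussianSpec = GaussianSpec(3e-4, 2e-4)
    #: Per animal-frame probability that a recumbent pig is falsely
    #: flagged as standing by the detector.
    false_detection_rate: float = 0.1
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if not self.state_schedule:
            raise ValueError("state_schedule is empty")
        starts = [t for t, _ in self.state_schedule]
        if starts[0] > 0:
            raise ValueError(
                "state_schedule must cover the stream from t=0 "
                f"(first state starts at {starts[0]})"
            )
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ValueError("schedule start times must be strictly increasing")
        for _, state in self.state_schedule:
            if state not in (ALL_RECUMBENT, SOME_ACTIVE):
                raise ValueError(f"unknown group state {state!r}")
        if self.n_active_when_active < 1:
            raise ValueError("n_active_when_active must be >= 1")
        if not 0.0 <= self.false_detection_rate <= 1.0:
            raise ValueError("false_detection_rate must be in [0, 1]")
        if self.active_speed_dist.mean <= self.recumbent_jitter_dist.mean:
            raise ValueError(
                "active speed mean must exceed recumbent jitter mean"
            )

    def state_at(self, t_s: float) -> str:
        starts = [s for s, _ in self.state_schedule]
        idx = int(np.searchsorted(starts, t_s, side="right")) - 1
        return self.state_schedule[max(idx, 0)][1]


def alternating_schedule(
    duration_s: float, period_s: float, first: str = SOME_ACTIVE
) -> tuple[tuple[float, str], ...]:
    """Build a schedule alternating between the two group states."""
    other = ALL_RECUMBENT if first == SOME_ACTIVE else SOME_ACTIVE
    starts = np.arange(0.0, duration_s, period_s)
    return tuple((float(t), first if i % 2 == 0 else other) for i, t in enumerate(starts))


@dataclass
class TrajectoryResult:
    """Tracked positions plus the ground-truth ethogram for one pen."""

    frames: pd.DataFrame  # pen_id, t_s, animal_id, x_m, y_m, detected_standing
    ethogram: pd.DataFrame  # pen_id, t_s, code
    n_clipped: int = 0


def _fold(x: np.ndarray, width: float) -> np.ndarray:
    """Reflect unbounded coordinates into [0, width] (triangle wave)."""
    m = np.mod(x, 2.0 * width)
    return np.where(m <= width, m, 2.0 * width - m)


def generate_trajectories(pen: PenConfig, scenario: BehaviorScenario) -> TrajectoryResult:
    """Simulate the tracker's per-frame output for one pen.

    Returns one frame per ``frame_interval_s`` tick over the scenario
    duration.  Recumbent animals take random-direction steps with
    magnitudes from the jitter distribution (detection noise); during
    active segments, ``n_active_when_active`` animals (chosen per segment)
    take steps with magnitudes from the activity distribution and are
    flagged as standing.  Positions that leave the pen are reflected back
    inside and counted as clipped.
    """
    rng = np.random.default_rng(scenario.seed)
    dt = pen.frame_interval_s
    n_frames = int(round(scenario.duration_s / dt))
    if n_frames < 1:
        raise ValueError("duration shorter than one frame interval")
    n = pen.n_animals
    times = np.arange(n_frames) * dt

    # Per-frame state index into the schedule.
    starts = np.array([s for s, _ in scenario.state_schedule])
    seg_idx = np.clip(np.searchsorted(starts, times, side="right") - 1, 0, None)
    states = np.array([scenario.state_schedule[i][1] for i in seg_idx])
    active_frame = states == SOME_ACTIVE

    # Step magnitudes: jitter everywhere, overridden for active animals.
    speed = scenario.recumbent_jitter_dist.sample(rng, (n_frames, n))
    standing = rng.random((n_frames, n)) < scenario.false_detection_rate

    # Choose the active subset once per contiguous active segment.
    for seg in np.unique(seg_idx[active_frame]):
        mask = seg_idx == seg
        movers = rng.choice(n, size=scenario.n_active_when_active, replace=False)
        speed[np.ix_(mask, movers)] = scenario.active_speed_dist.sample(
            rng, (int(mask.sum()), scenario.n_active_when_active)
        )
        standing[np.ix_(mask, movers)] = True

    theta = rng.uniform(0.0, 2.0 * math.pi, size=(n_frames, n))
    step = speed * dt
    dx = step * np.cos(theta)
    dy = step * np.sin(theta)
    # Frame 0 is the initial position; steps apply from frame 1 on.
    dx[0] = 0.0
    dy[0] = 0.0

    x0 = rng.uniform(0.0, pen.width_m, size=n)
    y0 = rng.uniform(0.0, pen.height_m, size=n)
    x_raw = x0 + np.cumsum(dx, axis=0)
    y_raw = y0 + np.cumsum(dy, axis=0)
    n_clipped = int(
        np.sum((x_raw < 0) | (x_raw > pen.width_m))
        + np.sum((y_raw < 0) | (y_raw > pen.height_m))
    )
    if n_clipped:
        logger.info(
            "pen %s: %d coordinates reflected back into pen bounds",
            pen.pen_id, n_clipped,
        )
    x = _fold(x_raw, pen.width_m)
    y = _fold(y_raw, pen.height_m)

    frames = pd.DataFrame(
        {
            "pen_id": pen.pen_id,
            "t_s": np.repeat(times, n),
            "animal_id": np.tile(np.arange(n), n_frames),
            "x_m": x.ravel(),
            "y_m": y.ravel(),
            "detected_standing": standing.ravel().astype(int),
        }
    )

    sample_times = np.arange(0.0, scenario.duration_s, pen.sampling_interval_s)
    codes = [1 if scenario.state_at(t) == SOME_ACTIVE else 0 for t in sample_times]
    ethogram = pd.DataFrame(
        {"pen_id": pen.pen_id, "t_s": sample_times, "code": codes}
    )
    return TrajectoryResult(frames=frames, ethogram=ethogram, n_clipped=n_clipped)


# ---------------------------------------------------------------------------
# Synthetic images

@dataclass(frozen=True)
class SyntheticImageSpec:
    """Recipe for one synthetic grayscale scene with controllable blur."""

    shape_count: int = 12
    intensity_range: tuple[float, float] = (0.0, 255.0)
    blur_sigma: float = 0.0
    size_px: tuple[int, int] = (96, 96)
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.blur_sigma < 0:
            raise ValueError("blur_sigma must be nonnegative")
        if self.size_px[0] < 8 or self.size_px[1] < 8:
            raise ValueError("size_px must be at least (8, 8)")
        if self.shape_count < 0:
            raise ValueError("shape_count must be nonnegative")
        lo, hi = self.intensity_range
        if hi < lo:
            raise ValueError("intensity_range must be (low, high)")


def generate_image(
    spec: SyntheticImageSpec, pen_id: str = "synthetic", t_s: float = 0.0
) -> ImageRecord:
    """Render a deterministic random-ellipse scene, then Gaussian-blur it.

    The same seed always yields the same base scene, so increasing
    ``blur_sigma`` only smooths that scene and cannot raise its expected
    Laplacian variance.  Pixels are float64 in ``intensity_range``.
    """
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.size_px
    lo, hi = spec.intensity_range
    img = np.full((rows, cols), lo, dtype=float)
    yy, xx = np.mgrid[0:rows, 0:cols]
    for _ in range(spec.shape_count):
        cy = rng.uniform(0, rows)
        cx = rng.uniform(0, cols)
        ay = rng.uniform(rows / 16, rows / 4)
        ax = rng.uniform(cols / 16, cols / 4)
        val = rng.uniform(lo, hi)
        mask = ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0
        img[mask] = val
    if spec.blur_sigma > 0:
        img = gaussian_filter(img, spec.blur_sigma, mode="nearest")
    img = np.clip(img, lo, hi)
    return ImageRecord(pen_id=pen_id, t_s=t_s, pixels=img)


def blur_ladder(base: SyntheticImageSpec, sigmas) -> list[ImageRecord]:
    """The same base scene rendered at each blur width in ``sigmas``."""
    return [generate_image(replace(base, blur_sigma=float(s))) for s in sigmas]


# ---------------------------------------------------------------------------
# Labeled datasets

@dataclass
class LabeledDataset:
    """Everything a full pipeline run consumes, with ground truth attached."""

    frames: pd.DataFrame
    ethogram: pd.DataFrame           # ground truth codes at sampling instants
    images: list[ImageRecord]
    coder_a: pd.DataFrame            # pen_id, t_s, coder_id, code
    coder_b: pd.DataFrame
    summary: dict = field(default_factory=dict)


def generate_labeled_dataset(
    pens: list[PenConfig],
    scenarios: list[BehaviorScenario],
    image_spec: SyntheticImageSpec | None = None,
    blur_sigmas: tuple[float, ...] = (0.0,),
    disagreement_rate: float = 0.0,
    n_disagreements: int | None = None,
    seed: int = DEFAULT_SEED,
) -> LabeledDataset:
    """Generate trajectories, sampled images and two-coder label tables.

    Coder A reproduces the ground-truth ethogram exactly.  Coder B flips
    each code independently with probability ``disagreement_rate``, or —
    if ``n_disagreements`` is given — flips exactly that many codes chosen
    uniformly without replacement.  Image blur widths cycle through
    ``blur_sigmas`` so a dataset can straddle the QC cutoff.
    """
    if not 0.0 <= disagreement_rate <= 1.0:
        raise ValueError("disagreement_rate must be in [0, 1]")
    if len(pens) != len(scenarios):
        raise ValueError("need one scenario per pen")
    image_spec = image_spec or SyntheticImageSpec()
    rng = np.random.default_rng(seed)

    frames_parts, etho_parts, images = [], [], []
    img_counter = 0
    for pen, scenario in zip(pens, scenarios):
        result = generate_trajectories(pen, scenario)
        frames_parts.append(result.frames)
        etho_parts.append(result.ethogram)
        for t in result.ethogram["t_s"]:
            sigma = blur_sigmas[img_counter % len(blur_sigmas)]
            spec = replace(
                image_spec,
                blur_sigma=float(sigma),
                seed=int((seed + 7919 * img_counter) % 2**31),
            )
            images.append(generate_image(spec, pen_id=pen.pen_id, t_s=float(t)))
            img_counter += 1
    frames = pd.concat(frames_parts, ignore_index=True)
    ethogram = pd.concat(etho_parts, ignore_index=True)

    coder_a = ethogram.assign(coder_id="A")[["pen_id", "t_s", "coder_id", "code"]]
    codes_b = ethogram["code"].to_numpy().copy()
    if n_disagreements is not None:
        if n_disagreements > len(codes_b):
            raise ValueError("n_disagreements exceeds label count")
        flip = rng.choice(len(codes_b), size=n_disagreements, replace=False)
        codes_b[flip] = 1 - codes_b[flip]
    else:
        flip_mask = rng.random(len(codes_b)) < disagreement_rate
        codes_b[flip_mask] = 1 - codes_b[flip_mask]
    coder_b = ethogram.assign(coder_id="B", code=codes_b)[
        ["pen_id", "t_s", "coder_id", "code"]
    ]

    summary = {
        "n_pens": len(pens),
        "n_frames": int(frames["t_s"].nunique()),
        "n_labels": int(len(ethogram)),
        "n_disagreements": int((coder_a["code"].to_numpy() != codes_b).sum()),
        "class_balance": {
            "standing": int((ethogram["code"] == 1).sum()),
            "recumbent": int((ethogram["code"] == 0).sum()),
        },
    }
    logger.info("labeled dataset: %s", summary)
    return LabeledDataset(frames, ethogram, images, coder_a, coder_b, summary)


# ---------------------------------------------------------------------------
# Direct two-population velocity samples (window-level shortcut)

def sample_velocity_dataset(
    n: int,
    recumbent_fraction: float = 411 / 3960,
    recumbent_sigma: float = 2e-4,
    active_mean: float = 5e-3,
    active_sd: float = 1.2e-3,
    seed: int = DEFAULT_SEED,
) -> pd.DataFrame:
    """Draw window-level group velocities directly from the two-state mixture.

    Recumbent windows carry only detection noise, |Normal(0, sigma0)|;
    active windows carry Normal(mu1, sigma1) clipped at 0.  The default
    class balance matches a heavily activity-dominated rearing dataset
    (~10% group recumbency).  Returns a frame with ``v_mps`` and ``code``.
    """
    if n < 2:
        raise ValueError("need at least two samples")
    rng = np.random.default_rng(seed)
    codes = (rng.random(n) >= recumbent_fraction).astype(int)
    v = np.where(
        codes == 0,
        np.abs(rng.normal(0.0, recumbent_sigma, n)),
        np.clip(rng.normal(active_mean, active_sd, n), 0.0, None),
    )
    return pd.DataFrame({"v_mps": v, "code": codes})


def bayes_accuracy(
    recumbent_fraction: float = 411 / 3960,
    recumbent_sigma: float = 2e-4,
    active_mean: float = 5e-3,
    active_sd: float = 1.2e-3,
) -> float:
    """Best achievable accuracy (%) of any velocity cutoff on the mixture.

    For cutoff t, accuracy(t) = pi0 * P(|N(0, s0)| <= t)
                              + pi1 * P(N(mu1, s1) > t);
    the maximum over t on a fine grid is returned.  This is the analytic
    ceiling a fitted threshold classifier is compared against.
    """
    pi0 = recumbent_fraction
    pi1 = 1.0 - pi0
    t = np.linspace(0.0, active_mean + 4 * active_sd, 20001)
    acc = pi0 * (2.0 * norm.cdf(t / recumbent_sigma) - 1.0) + pi1 * (
        1.0 - norm.cdf((t - active_mean) / active_sd)
    )
    return float(100.0 * acc.max())
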