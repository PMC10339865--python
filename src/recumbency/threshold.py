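"""Velocity-cutoff classifiers separating group recumbency from activity.

The classifier is a single cutoff on the 5-minute group velocity: a window
is called active (code 1) iff its velocity strictly exceeds the threshold;
a velocity exactly at the threshold is called recumbent, which favors the
detector's goal of only ever surfacing genuinely all-recumbent images.

Three fitters are provided:

``fit_exhaustive``
    The canonical fitter: evaluates every decision boundary (midpoints
    between consecutive distinct sorted velocities, plus one candidate
    below the minimum and one above the maximum) and returns the one
    maximizing training accuracy.  Ties are broken toward higher
    sensitivity, then toward the smaller threshold.

``fit_paper_loop``
    A stepwise search: starting from the smallest velocity, the cutoff is
    raised in fixed increments while the count of active-coded samples
    above it keeps strictly decreasing; if the resulting cutoff is below
    the highest recumbent-coded velocity, the search restarts from that
    value.  Kept as a faithful secondary implementation of a narrative
    procedure whose step size and stopping rule admit several readings.

``fit_mean_plus_sd``
    Mean of the recumbent-class velocities plus one sample standard
    deviation — the simple screening rule used before any labeled data
    exist.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

RULE = "standing (1) iff v > threshold_mps"


@dataclass(frozen=True)
class ThresholdModel:
    """A fitted velocity cutoff; classification rule is ``v > threshold``."""

    threshold_mps: float
    method: str
    fitted_on_n: int = 0
    rule: str = RULE

    def to_dict(self) -> dict:
        return {
            "threshold_mps": self.threshold_mps,
            "method": self.method,
            "fitted_on_n": self.fitted_on_n,
            "rule": self.rule,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ThresholdModel":
        return cls(
            threshold_mps=float(d["threshold_mps"]),
            method=str(d["method"]),
            fitted_on_n=int(d.get("fitted_on_n", 0)),
        )


Fitter = Callable[[np.ndarray, np.ndarray], ThresholdModel]


def classify(v, model: ThresholdModel):
    """Code 1 (standing) iff velocity strictly exceeds the threshold.

    Accepts a scalar or an array; a velocity exactly at the threshold is
    assigned code 0 (recumbent).
    """
    arr = np.asarray(v)
    out = (arr > model.threshold_mps).astype(int)
    return int(out) if np.isscalar(v) or arr.ndim == 0 else out


def _validate_samples(v, codes) -> tuple[np.ndarray, np.ndarray]:
    v = np.asarray(v, dtype=float)
    codes = np.asarray(codes, dtype=int)
    if v.shape != codes.shape or v.ndim != 1:
        raise ValueError("v and codes must be 1-D arrays of equal length")
    if not np.isin(codes, [0, 1]).all():
        raise ValueError("codes must be 0 or 1")
    if (v < 0).any():
        raise ValueError("velocities must be nonnegative")
    if codes.min() == codes.max():
        raise ValueError("need at least one sample of each class to fit a threshold")
    return v, codes


def _boundary_stats(v: np.ndarray, codes: np.ndarray):
    """Candidate thresholds between distinct velocities with accuracy stats.

    Returns (thresholds, n_correct, sensitivity) over cuts i = 0..m where
    cut i places the i smallest distinct velocity groups at or below the
    threshold (predicted 0) and the rest above (predicted 1).
    """
    u, inv = np.unique(v, return_inverse=True)
    m = len(u)
    ones_per_value = np.bincount(inv, weights=codes, minlength=m)
    count_per_value = np.bincount(inv, minlength=m)
    total1 = codes.sum()
    # ones_below[i] / n_below[i]: counts among the i smallest distinct values.
    ones_below = np.concatenate([[0.0], np.cumsum(ones_per_value)])
    n_below = np.concatenate([[0.0], np.cumsum(count_per_value)])
    zeros_below = n_below - ones_below          # correct predictions of class 0
    ones_above = total1 - ones_below            # correct predictions of class 1
    n_correct = zeros_below + ones_above
    sensitivity = ones_above / total1
    # Threshold realizing cut i: below min, midpoints, above max.
    span = u[-1] - u[0]
    margin = span / 2 if span > 0 else max(abs(u[0]), 1.0)
    thresholds = np.concatenate([[u[0] - margin], (u[:-1] + u[1:]) / 2.0, [u[-1] + margin]])
    return thresholds, n_correct, sensitivity


def fit_exhaustive(v, codes) -> ThresholdModel:
    """Accuracy-maximizing cutoff over all distinct decision boundaries.

    Candidates are midpoints between consecutive distinct sorted
    velocities plus one candidate below the minimum and one above the
    maximum; ties in training accuracy are broken toward higher
    sensitivity, then toward the smaller threshold.  Requires both classes
    present.
    """
    v, codes = _validate_samples(v, codes)
    thresholds, n_correct, sens = _boundary_stats(v, codes)
    best_acc = n_correct.max()
    tied = np.flatnonzero(n_correct == best_acc)
    # Sensitivity is nonincreasing in the cut index, so the first tied cut
    # maximizes sensitivity; it also has the smallest threshold.
    pick = tied[0]
    return ThresholdModel(
        threshold_mps=float(thresholds[pick]),
        method="exhaustive",
        fitted_on_n=len(v),
    )


def fit_paper_loop(v, codes, step: float, init: float | None = None) -> ThresholdModel:
    """Stepwise threshold search over ascending-sorted velocities.

    From ``init`` (default: smallest velocity) the cutoff grows by ``step``
    while each increment strictly decreases the number of active-coded
    samples above it; when it stops decreasing the cutoff is recorded.  If
    the recorded cutoff lies below the highest recumbent-coded velocity,
    the search restarts from that velocity.  ``step`` must not exceed the
    velocity range.
    """
    v, codes = _validate_samples(v, codes)
    if step <= 0:
        raise ValueError("step must be positive")
    v_range = float(v.max() - v.min())
    if v_range > 0 and step > v_range:
        raise ValueError(f"step {step} larger than the velocity range {v_range}")

    def n_active_above(t: float) -> int:
        return int(np.sum((codes == 1) & (v > t)))

    t = float(v.min()) if init is None else float(init)
    highest_recumbent = float(v[codes == 0].max())
    while True:
        while n_active_above(t + step) < n_active_above(t):
            t += step
        if t < highest_recumbent:
            t = highest_recumbent
            continue
        break
    return ThresholdModel(threshold_mps=t, method="paper_loop", fitted_on_n=len(v))


def fit_mean_plus_sd(recumbent_velocities) -> ThresholdModel:
    """Mean + one sample standard deviation of the recumbent-class velocities."""
    v = np.asarray(recumbent_velocities, dtype=float)
    if v.ndim != 1 or len(v) < 2:
        raise ValueError("need at least two recumbent velocities")
    if (v < 0).any():
        raise ValueError("velocities must be nonnegative")
    thr = float(v.mean() + v.std(ddof=1))
    return ThresholdModel(threshold_mps=thr, method="mean_plus_sd", fitted_on_n=len(v))


FITTERS: dict[str, Fitter] = {
    "exhaustive": fit_exhaustive,
}


def training_accuracy(v, codes, model: ThresholdModel) -> float:
    """Fraction of samples the model classifies correctly (0..1)."""
    v = np.asarray(v, dtype=float)
    codes = np.asarray(codes, dtype=int)
    return float(np.mean(classify(v, model) == codes))
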