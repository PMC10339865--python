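"""Confusion-matrix metrics, k-fold cross-validation, and the velocity t-test.

Positive class is "standing" (code 1): TP is a standing-labeled window
classified standing, TN a recumbent-labeled window classified recumbent.

    sensitivity = TP / (TP + FN)
    specificity = TN / (TN + FP)
    accuracy    = (TP + TN) / (TP + FP + TN + FN)

All metrics are reported in percent at full precision; rounding happens
only at report time.  A metric whose denominator is zero is *undefined*
(``None``), never 0, and undefined per-fold values are excluded from the
cross-validation averages (the exclusion is logged).

Cross-validation shuffles once with the given seed, splits into k folds
whose sizes differ by at most one, fits the threshold on the k-1 training
folds and evaluates on the held-out fold; averages across folds are
unweighted.

The class-separation check is a Welch (unequal-variance) two-sample
t-test on velocity by code — Welch because the two classes are grossly
unbalanced in both size and spread.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import KFold

from .threshold import Fitter, ThresholdModel, classify, fit_exhaustive

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def to_dict(self) -> dict:
        return {"tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn}


@dataclass(frozen=True)
class Metrics:
    """Percentage metrics; ``None`` marks an undefined (0-denominator) value."""

    sensitivity_pct: float | None
    specificity_pct: float | None
    accuracy_pct: float

    def to_dict(self) -> dict:
        return {
            "sensitivity_pct": self.sensitivity_pct,
            "specificity_pct": self.specificity_pct,
            "accuracy_pct": self.accuracy_pct,
        }


def confusion(codes_true, codes_pred) -> ConfusionCounts:
    """Tally the 2x2 confusion table with standing (1) as positive class."""
    t = np.asarray(codes_true, dtype=int)
    p = np.asarray(codes_pred, dtype=int)
    if t.shape != p.shape:
        raise ValueError("label arrays differ in length")
    return ConfusionCounts(
        tp=int(np.sum((t == 1) & (p == 1))),
        fp=int(np.sum((t == 0) & (p == 1))),
        tn=int(np.sum((t == 0) & (p == 0))),
        fn=int(np.sum((t == 1) & (p == 0))),
    )


def metrics(c: ConfusionCounts) -> Metrics:
    """Sensitivity, specificity and accuracy in percent from counts."""
    if c.total == 0:
        raise ValueError("empty confusion table")
    sens = 100.0 * c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else None
    spec = 100.0 * c.tn / (c.tn + c.fp) if (c.tn + c.fp) > 0 else None
    acc = 100.0 * (c.tp + c.tn) / c.total
    return Metrics(sensitivity_pct=sens, specificity_pct=spec, accuracy_pct=acc)


@dataclass(frozen=True)
class FoldResult:
    fold: int
    threshold_mps: float
    counts: ConfusionCounts
    metrics: Metrics

    def to_dict(self) -> dict:
        return {
            "fold": self.fold,
            "threshold_mps": self.threshold_mps,
            "counts": self.counts.to_dict(),
            **self.metrics.to_dict(),
        }


@dataclass
class EvalReport:
    """Per-fold thresholds/metrics and their unweighted averages."""

    k: int
    seed: int
    method: str
    folds: list[FoldResult]
    averages: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "seed": self.seed,
            "method": self.method,
            "folds": [f.to_dict() for f in self.folds],
            "averages": self.averages,
        }


def _average(values: list[float | None], name: str) -> float | None:
    defined = [x for x in values if x is not None]
    if len(defined) < len(values):
        logger.info(
            "%s undefined in %d of %d folds; excluded from the average",
            name, len(values) - len(defined), len(values),
        )
    return float(np.mean(defined)) if defined else None


def cross_validate(
    samples: pd.DataFrame,
    k: int = 10,
    seed: int = 123,
    fitter: Fitter = fit_exhaustive,
) -> EvalReport:
    """Seeded k-fold cross-validation of a velocity-threshold fitter.

    ``samples`` must carry columns ``v_mps`` and ``code``.  Each fold
    serves as test set once; the threshold is refitted on the remaining
    folds each time.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    v = samples["v_mps"].to_numpy(dtype=float)
    codes = samples["code"].to_numpy(dtype=int)
    n = len(v)
    if n < k:
        raise ValueError(f"need at least k={k} samples, got {n}")
    if codes.min() == codes.max():
        raise ValueError("both classes must be present overall")

    folds: list[FoldResult] = []
    splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    for i, (train, test) in enumerate(splitter.split(v)):
        model = fitter(v[train], codes[train])
        pred = classify(v[test], model)
        c = confusion(codes[test], pred)
        folds.append(FoldResult(i, model.threshold_mps, c, metrics(c)))

    averages = {
        "threshold_mps": float(np.mean([f.threshold_mps for f in folds])),
        "sensitivity_pct": _average([f.metrics.sensitivity_pct for f in folds], "sensitivity"),
        "specificity_pct": _average([f.metrics.specificity_pct for f in folds], "specificity"),
        "accuracy_pct": _average([f.metrics.accuracy_pct for f in folds], "accuracy"),
    }
    method = getattr(fitter, "__name__", "custom")
    return EvalReport(k=k, seed=seed, method=method, folds=folds, averages=averages)


@dataclass(frozen=True)
class TTestResult:
    t_statistic: float
    p_value: float
    mean_standing_mps: float
    mean_recumbent_mps: float

    def to_dict(self) -> dict:
        return {
            "t_statistic": self.t_statistic,
            "p_value": self.p_value,
            "mean_standing_mps": self.mean_standing_mps,
            "mean_recumbent_mps": self.mean_recumbent_mps,
        }


def velocity_ttest(samples: pd.DataFrame) -> TTestResult:
    """Welch two-sample t-test of velocity between the two behavior codes.

    Two-sided; significance is conventionally read at alpha = 0.05.
    Requires at least two samples per class.
    """
    v1 = samples.loc[samples["code"] == 1, "v_mps"].to_numpy(dtype=float)
    v0 = samples.loc[samples["code"] == 0, "v_mps"].to_numpy(dtype=float)
    if len(v0) < 2 or len(v1) < 2:
        raise ValueError("need at least two samples in each class")
    res = stats.ttest_ind(v1, v0, equal_var=False)
    return TTestResult(
        t_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        mean_standing_mps=float(v1.mean()),
        mean_recumbent_mps=float(v0.mean()),
    )


def accuracy_curve(samples: pd.DataFrame, thresholds) -> pd.DataFrame:
    """Classification accuracy (%) at each candidate threshold.

    The maximum of this curve over the exhaustive candidate set equals
    the training accuracy of :func:`~recumbency.threshold.fit_exhaustive`.
    """
    thr = np.asarray(thresholds, dtype=float)
    if thr.ndim != 1 or len(thr) == 0:
        raise ValueError("need at least one candidate threshold")
    v = samples["v_mps"].to_numpy(dtype=float)
    codes = samples["code"].to_numpy(dtype=int)
    acc = [
        100.0 * np.mean(((v > t).astype(int)) == codes)
        for t in thr
    ]
    return pd.DataFrame({"threshold_mps": thr, "accuracy_pct": acc})
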