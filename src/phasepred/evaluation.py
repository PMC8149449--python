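"""Prediction accuracy metrics, model comparison statistics, the bedtime
heuristic, and classification scoring.

Errors are (predicted - actual) DLMO in minutes on the linearized clock
axis. Accuracy is summarised by mean error, mean absolute error, RMSE, and
the count/percentage of participants predicted within +/- 0.5, 1, 1.5 and
2 h (half-open shells; an error exactly on an edge belongs to the tighter
band). Correlations between models are compared with Fisher's r-to-z, and
regression slopes with a normal test on their difference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .clock import linearize, wrap_diff_hours

BAND_EDGES_MIN = (30.0, 60.0, 90.0, 120.0)
BAND_LABELS = ("within_0.5h", "within_1h", "within_1.5h", "within_2h", "over_2h")


@dataclass
class EvalReport:
    """Accuracy summary for one model on one dataset (all time units min)."""

    n: int
    mean_error: float
    sd_error: float
    mean_abs_error: float
    sd_abs_error: float
    rmse: float
    band_counts: dict[str, int]
    band_percents: dict[str, float]
    cumulative_counts: dict[str, int]
    cumulative_percents: dict[str, float]
    pearson_r: float | None = None
    r_squared: float | None = None
    slope: float | None = None
    slope_se: float | None = None

    def as_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


@dataclass
class ClassReport:
    """Confusion-matrix summary; the positive class is *circadian*."""

    tp: int
    fn: int
    fp: int
    tn: int
    sensitivity: float
    specificity: float
    f1: float
    accuracy: float

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    def as_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


def prediction_errors_min(pred, actual) -> np.ndarray:
    """(predicted - actual) in minutes, wrapped on the clock."""
    pred = np.asarray(pred, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if pred.shape != actual.shape:
        raise ValueError("predicted and actual arrays must have equal length")
    return wrap_diff_hours(pred, actual) * 60.0


def error_metrics(pred, actual) -> EvalReport:
    """Mean error, MAE, RMSE and accuracy-band counts for paired DLMO times."""
    err = prediction_errors_min(pred, actual)
    n = err.size
    if n < 2:
        raise ValueError("need at least two prediction pairs")
    abs_err = np.abs(err)

    shells = np.digitize(abs_err, BAND_EDGES_MIN, right=True)
    counts = {lab: int((shells == i).sum()) for i, lab in enumerate(BAND_LABELS)}
    cum, cum_counts = 0, {}
    for lab in BAND_LABELS:
        cum += counts[lab]
        cum_counts[lab] = cum
    return EvalReport(
        n=n,
        mean_error=float(err.mean()), sd_error=float(err.std(ddof=1)),
        mean_abs_error=float(abs_err.mean()), sd_abs_error=float(abs_err.std(ddof=1)),
        rmse=float(np.sqrt(np.mean(err ** 2))),
        band_counts=counts,
        band_percents={k: 100.0 * v / n for k, v in counts.items()},
        cumulative_counts=cum_counts,
        cumulative_percents={k: 100.0 * v / n for k, v in cum_counts.items()},
    )


def correlate(pred, actual) -> tuple[float, float, float, float]:
    """Pearson r, R^2, and the slope (with SE) of predicted on actual."""
    pred = np.asarray(pred, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if pred.size < 3:
        raise ValueError("need at least three pairs")
    if np.std(pred) == 0 or np.std(actual) == 0:
        raise ValueError("zero variance in predicted or actual times")
    res = stats.linregress(actual, pred)
    return (float(res.rvalue), float(res.rvalue ** 2),
            float(res.slope), float(res.stderr))


def fisher_rz(r1: float, n1: int, r2: float, n2: int) -> tuple[float, float]:
    """Compare two independent Pearson correlations via Fisher's r-to-z.

    z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3)), two-sided
    normal p. Note the antisymmetry fisher_rz(r1,.,r2,.) = -fisher_rz(r2,.,r1,.).
    """
    for r, n in ((r1, n1), (r2, n2)):
        if abs(r) >= 1.0:
            raise ValueError("|r| must be < 1 for the z transform")
        if n <= 3:
            raise ValueError("need n > 3")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def compare_slopes(b1: float, se1: float, b2: float, se2: float
                   ) -> tuple[float, float]:
    """Normal test on the difference of two regression slopes."""
    denom = np.sqrt(se1 ** 2 + se2 ** 2)
    if denom == 0:
        if b1 == b2:
            return 0.0, 1.0
        raise ZeroDivisionError("slope SEs are zero with unequal slopes")
    z = (b1 - b2) / denom
    return float(z), float(2.0 * stats.norm.sf(abs(z)))


def bedtime_heuristic(mean_bedtime: float) -> float:
    """Predict DLMO as mean actigraphic bedtime minus 2 h, the average
    DLMO-bedtime phase angle reported in healthy populations."""
    return linearize(mean_bedtime - 2.0)


def classification_metrics(pred_labels, true_labels,
                           positive: str = "circadian") -> ClassReport:
    """Sensitivity, specificity, F1 and accuracy with circadian positive."""
    pred = np.asarray(pred_labels)
    true = np.asarray(true_labels)
    if pred.shape != true.shape:
        raise ValueError("label arrays must have equal length")
    p, t = pred == positive, true == positive
    tp = int((p & t).sum())
    fn = int((~p & t).sum())
    fp = int((p & ~t).sum())
    tn = int((~p & ~t).sum())
    if tp + fn == 0:
        raise ValueError("no positive (circadian) cases in truth; "
                         "sensitivity undefined")
    sens = tp / (tp + fn)
    spec = tn / (tn + fp) if tn + fp else float("nan")
    prec = tp / (tp + fp) if tp + fp else 0.0
    f1 = 2 * prec * sens / (prec + sens) if prec + sens else 0.0
    return ClassReport(tp=tp, fn=fn, fp=fp, tn=tn,
                       sensitivity=sens, specificity=spec, f1=f1,
                       accuracy=(tp + tn) / (tp + fn + fp + tn))
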