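"""Prediction quality indicators and the two standard analysis experiments.

Four base indicators compare a predicted sequence with the truth: MAE and
RMSE measure numerical error, Pearson and Spearman correlation measure trend
agreement.  A *composite indicator* summarizes all four comparatively across
a set of predictions: each criterion is min-max normalized over the set
(errors inverted so that higher is always better) and the four normalized
scores are averaged, giving a value in [0, 1].

``window_scan`` probes the time-invariance assumption: the map from states to
delay coordinates is only approximately constant over a short window, so
prediction quality as a function of training-window length typically rises
(more data) and then falls (the dynamics drift).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats as sps

from .embedding import MultivariateSeries
from .network import ALMConfig, fit_predict

__all__ = [
    "EvaluationReport",
    "compute_indicators",
    "composite_indicator",
    "window_scan",
]


@dataclass
class EvaluationReport:
    """MAE, RMSE, Pearson and Spearman for one prediction/truth pair.

    Correlations are NaN (and ``degenerate`` is True) when either sequence
    has zero variance — undefined, not zero.  ``composite`` is filled only by
    :func:`composite_indicator`, which is comparative by construction.
    """

    mae: float
    rmse: float
    pearson: float
    spearman: float
    degenerate: bool = False
    composite: float | None = None


def compute_indicators(truth, predicted) -> EvaluationReport:
    """MAE = mean |e|, RMSE = sqrt(mean e^2), sample Pearson, and Spearman
    (Pearson of average ranks)."""
    t = np.asarray(truth, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if t.shape != p.shape or t.ndim != 1:
        raise ValueError("truth and predicted must be 1-D sequences of equal length")
    if len(t) < 2:
        raise ValueError("need at least 2 points")
    e = p - t
    mae = float(np.abs(e).mean())
    rmse = float(np.sqrt((e ** 2).mean()))
    if t.std() < 1e-300 or p.std() < 1e-300:
        return EvaluationReport(mae=mae, rmse=rmse, pearson=float("nan"),
                                spearman=float("nan"), degenerate=True)
    pearson = float(sps.pearsonr(t, p).statistic)
    spearman = float(sps.spearmanr(t, p).statistic)
    return EvaluationReport(mae=mae, rmse=rmse, pearson=pearson, spearman=spearman)


def composite_indicator(reports: list[EvaluationReport]) -> list[float]:
    """Comparative score in [0, 1]: per criterion, min-max normalize across
    the reports (MAE and RMSE inverted), then average the normalized scores.

    A criterion that is identical across all reports contributes the neutral
    value 0.5.  A criterion undefined (NaN) in any report is excluded for all
    reports.  Results are also written into each report's ``composite``.
    """
    if len(reports) < 2:
        raise ValueError("the composite indicator is comparative: need >= 2 reports")
    criteria = {
        "mae": (np.array([r.mae for r in reports]), True),
        "rmse": (np.array([r.rmse for r in reports]), True),
        "pearson": (np.array([r.pearson for r in reports]), False),
        "spearman": (np.array([r.spearman for r in reports]), False),
    }
    scores = []
    for vals, invert in criteria.values():
        if np.any(~np.isfinite(vals)):
            continue  # undefined for some report: excluded for all
        lo, hi = vals.min(), vals.max()
        if hi - lo < 1e-300:
            s = np.full(len(vals), 0.5)
        else:
            s = (vals - lo) / (hi - lo)
            if invert:
                s = 1.0 - s
        scores.append(s)
    if not scores:
        raise ValueError("all criteria are undefined; nothing to composite")
    comp = np.mean(scores, axis=0)
    for r, c in zip(reports, comp):
        r.composite = float(c)
    return [float(c) for c in comp]


def window_scan(series: MultivariateSeries, target_k, window_lengths,
                config: ALMConfig, test_points: int = 10) -> dict[int, EvaluationReport]:
    """Train on the most recent w points preceding a fixed test segment (the
    last ``test_points`` points of the series), predict that segment, and
    evaluate — once per window length w.

    The prediction horizon is forced to ``test_points`` and L is enlarged to
    at least ``test_points + 1`` if the supplied config is smaller.  Results
    are deterministic under the config seed and independent of the ordering
    of ``window_lengths``.
    """
    M = series.M
    k = series.variable_index(target_k)
    windows = [int(w) for w in window_lengths]
    feasible = [w for w in windows if w + test_points <= M and w >= 2]
    if len(feasible) != len(windows):
        raise ValueError(
            f"window lengths {sorted(set(windows) - set(feasible))} infeasible for "
            f"M={M} with {test_points} test points; feasible: w in [2, {M - test_points}]"
        )
    truth = series.values[k, M - test_points:]
    base = replace(config, horizon=test_points, L=max(config.L, test_points + 1))
    out: dict[int, EvaluationReport] = {}
    for w in windows:
        train = series.window(M - test_points - w, M - test_points)
        res = fit_predict(train, k, base)
        out[w] = compute_indicators(truth, res.values)
    return out
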