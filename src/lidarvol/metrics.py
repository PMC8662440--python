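"""Detection and regression accuracy metrics for tree extraction.

Detected trees are scored against a reference tree list: a detection is
correct when it falls inside the crown of a reference tree, matches are
one-to-one, and the counts feed recall ``r = Nt/(Nt+No)``, precision
``p = Nt/(Nt+Nc)`` and overall accuracy ``F = 2rp/(r+p)``. Continuous
attributes (height, DBH, diameters, volumes) are scored with R², MAE, RMSE
and relative RMSE.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import numpy as np


def round_half_up(x: float, decimals: int = 2) -> float:
    """Round with ties going away from zero, as printed report tables do."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class DetectionMetrics:
    """Tree-detection score from matched/omitted/commission counts.

    ``n_matched`` (Nt) detections that hit a reference tree, ``n_omitted``
    (No) reference trees with no detection, ``n_commission`` (Nc) detections
    with no reference tree. ``r``/``p``/``f`` are reported rounded half-up
    to two decimals; ``recall``/``precision``/``f_score`` are exact.
    """

    n_matched: int
    n_omitted: int
    n_commission: int

    @property
    def recall(self) -> float:
        return self.n_matched / (self.n_matched + self.n_omitted)

    @property
    def precision(self) -> float:
        return self.n_matched / (self.n_matched + self.n_commission)

    @property
    def f_score(self) -> float:
        r, p = self.recall, self.precision
        return 2 * r * p / (r + p)

    @property
    def r(self) -> float:
        return round_half_up(self.recall)

    @property
    def p(self) -> float:
        return round_half_up(self.precision)

    @property
    def f(self) -> float:
        return round_half_up(self.f_score)


@dataclass(frozen=True)
class FitStats:
    """Goodness-of-fit of predictions against observations.

    ``rrmse`` is RMSE as a percentage of the observed mean.
    """

    r2: float
    mae: float
    rmse: float
    rrmse: float


def match_detections(
    detected: Sequence[tuple[float, float]],
    reference: Sequence[tuple[float, float, float]],
) -> tuple[int, int, int, list[tuple[int, int]]]:
    """Match detected positions to reference trees one-to-one.

    A candidate pair is valid when the horizontal distance from the detection
    to the reference stem does not exceed that reference's crown radius.
    Pairs are accepted greedily in ascending distance order (ties broken by
    detection index, then reference index), each detection and reference
    used at most once.

    Returns ``(Nt, No, Nc, pairs)`` where ``pairs`` holds
    ``(detected_index, reference_index)`` tuples.
    """
    det = np.asarray(detected, dtype=float).reshape(-1, 2)
    ref = np.asarray(reference, dtype=float).reshape(-1, 3)
    if len(ref) and np.any(ref[:, 2] <= 0):
        raise ValueError("crown radii must be positive")
    if len(ref) == 0 or len(det) == 0:
        return 0, len(ref), len(det), []

    d = np.hypot(
        det[:, 0][:, None] - ref[:, 0][None, :],
        det[:, 1][:, None] - ref[:, 1][None, :],
    )
    di, ri = np.nonzero(d <= ref[:, 2][None, :])
    order = np.lexsort((ri, di, d[di, ri]))
    pairs: list[tuple[int, int]] = []
    used_det = np.zeros(len(det), dtype=bool)
    used_ref = np.zeros(len(ref), dtype=bool)
    for k in order:
        i, j = int(di[k]), int(ri[k])
        if not used_det[i] and not used_ref[j]:
            used_det[i] = used_ref[j] = True
            pairs.append((i, j))
    nt = len(pairs)
    return nt, len(ref) - nt, len(det) - nt, pairs


def detection_metrics(nt: int, no: int, nc: int) -> DetectionMetrics:
    """Build :class:`DetectionMetrics`, rejecting undefined ratios."""
    if nt + no <= 0 or nt + nc <= 0:
        raise ValueError("detection metrics undefined: need Nt+No > 0 and Nt+Nc > 0")
    return DetectionMetrics(n_matched=nt, n_omitted=no, n_commission=nc)


def species_summary(plot_metrics: Iterable[DetectionMetrics | float]) -> float:
    """Species-level overall accuracy: mean of the rounded plot-level F values.

    Each plot F is rounded to two decimals before averaging, matching how
    per-plot report values are carried into the species column; the mean is
    rounded half-up to two decimals.
    """
    fs = [m.f if isinstance(m, DetectionMetrics) else round_half_up(float(m)) for m in plot_metrics]
    if not fs:
        raise ValueError("no plot metrics given")
    return round_half_up(sum(fs) / len(fs))


def regression_metrics(observed: Sequence[float], predicted: Sequence[float]) -> FitStats:
    """R², MAE, RMSE and relative RMSE of predictions against observations."""
    obs = np.asarray(observed, dtype=float).ravel()
    pred = np.asarray(predicted, dtype=float).ravel()
    if obs.shape != pred.shape or obs.size < 2:
        raise ValueError("observed and predicted must have equal length >= 2")
    mean_obs = obs.mean()
    if mean_obs == 0:
        raise ValueError("rRMSE undefined: observed mean is zero")
    sst = float(np.sum((obs - mean_obs) ** 2))
    if sst == 0:
        raise ValueError("R^2 undefined: observed values have zero variance")
    resid = obs - pred
    sse = float(np.sum(resid**2))
    rmse = float(np.sqrt(sse / obs.size))
    return FitStats(
        r2=1.0 - sse / sst,
        mae=float(np.mean(np.abs(resid))),
        rmse=rmse,
        rrmse=100.0 * rmse / mean_obs,
    )
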