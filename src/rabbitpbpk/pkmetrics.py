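"""PK endpoints (AUC, Cmax) and predictive-performance statistics.

The error conventions match common model-qualification practice:

* percent AUC error uses the *model* value as denominator,
  100 * |observed - predicted| / predicted;
* fold error is max(observed/predicted, predicted/observed), >= 1;
* the mean fold error over a validation set is the geometric mean of the
  per-case fold errors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np


class DomainError(ValueError):
    pass


@dataclass
class PKMetrics:
    AUC: float  # concentration * min
    Cmax: float
    tmax: float  # min
    extrapolated_fraction: float = 0.0


def _check_series(times: Sequence[float], concs: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    c = np.asarray(concs, dtype=float)
    if t.size < 2:
        raise DomainError("AUC/Cmax need at least 2 points")
    if np.any(np.diff(t) <= 0):
        raise DomainError("times must be strictly increasing")
    if np.any(c < 0):
        raise DomainError("concentrations must be >= 0")
    return t, c


def auc(
    times: Sequence[float],
    concs: Sequence[float],
    extrapolate: bool = False,
    n_terminal: int = 3,
) -> tuple[float, float]:
    """Linear trapezoidal AUC(0 -> t_last), optionally extrapolated to infinity.

    Extrapolation adds C_last / lambda_z with the terminal slope lambda_z
    from a log-linear least-squares fit of the last ``n_terminal`` (>= 3)
    positive observations. Returns ``(AUC, extrapolated_fraction)``.
    """
    t, c = _check_series(times, concs)
    base = float(np.trapezoid(c, t))
    if not extrapolate:
        return base, 0.0
    pos = c > 0
    if pos.sum() < max(3, n_terminal):
        raise DomainError("terminal extrapolation needs >= 3 positive concentrations")
    tt, cc = t[pos][-n_terminal:], c[pos][-n_terminal:]
    slope, _ = np.polyfit(tt, np.log(cc), 1)
    lam = -slope
    if lam <= 0:
        raise DomainError("terminal phase is not declining; cannot extrapolate")
    tail = float(c[-1] / lam) if c[-1] > 0 else float(cc[-1] / lam)
    total = base + tail
    return total, tail / total


def cmax(times: Sequence[float], concs: Sequence[float]) -> tuple[float, float]:
    """Maximum observed concentration and its time (first occurrence on ties)."""
    t, c = _check_series(times, concs)
    i = int(np.argmax(c))
    return float(c[i]), float(t[i])


def percent_auc_error(observed: float, predicted: float) -> float:
    """100 * |observed - predicted| / predicted (denominator = model value)."""
    if predicted <= 0:
        raise DomainError(f"predicted AUC must be > 0, got {predicted}")
    return 100.0 * abs(observed - predicted) / predicted


def fold_error(observed: float, predicted: float) -> float:
    """Symmetric fold error max(obs/pred, pred/obs), always >= 1."""
    if observed <= 0 or predicted <= 0:
        raise DomainError("fold error needs positive observed and predicted values")
    return max(observed / predicted, predicted / observed)


def mean_fold_error(pairs: Iterable[tuple[float, float]]) -> float:
    """Geometric mean of per-pair fold errors."""
    folds = [fold_error(o, p) for o, p in pairs]
    if not folds:
        raise DomainError("mean fold error of an empty set is undefined")
    return math.exp(sum(math.log(f) for f in folds) / len(folds))


def simulation_metrics(result, compartment: str = "venous_plasma", extrapolate: bool = True) -> PKMetrics:
    """PK endpoints of a simulated profile on the dense solver grid."""
    c = result.concentration(compartment)
    a, frac = auc(result.times, c, extrapolate=extrapolate)
    cm, tm = cmax(result.times, c)
    return PKMetrics(AUC=a, Cmax=cm, tmax=tm, extrapolated_fraction=frac)
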