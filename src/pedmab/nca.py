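"""Non-compartmental PK metrics and fold-error comparison statistics.

Conventions: linear-up/log-down trapezoidal AUC; terminal slope from a
log-linear regression over the best terminal subset (>=3 points after Tmax,
chosen by adjusted R²); extrapolation to infinity via C_last/λz.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .exceptions import DomainError


@dataclass(frozen=True)
class PKMetrics:
    """Non-compartmental summary of one concentration-time profile."""

    cmax: float                       # μg/mL
    tmax: float                       # days
    auc_0_t: float                    # μg·day/mL
    auc_0_inf: Optional[float]        # μg·day/mL; None if λz not estimable
    t_half: Optional[float]           # days
    clearance: Optional[float]        # mL/day/kg; needs dose, weight, AUC_inf
    lambda_z: Optional[float] = None  # 1/day
    n_lambda_points: int = 0


def _auc_lin_up_log_down(t: np.ndarray, c: np.ndarray) -> float:
    dt = np.diff(t)
    c1, c2 = c[:-1], c[1:]
    seg = 0.5 * (c1 + c2) * dt  # linear-up (and flat/zero) segments
    down = (c1 > 0) & (c2 > 0) & (c2 < c1)
    seg[down] = (c1[down] - c2[down]) * dt[down] / np.log(c1[down] / c2[down])
    return float(seg.sum())


def _terminal_fit(t: np.ndarray, c: np.ndarray):
    """Best terminal log-linear fit: (λz, n_points) or (None, 0)."""
    i_max = int(np.argmax(c))
    cand = [(ti, ci) for ti, ci in zip(t[i_max + 1:], c[i_max + 1:]) if ci > 0]
    if len(cand) < 3:
        return None, 0
    tt = np.array([x[0] for x in cand])
    lc = np.log(np.array([x[1] for x in cand]))
    best = (None, 0, -np.inf)
    for n in range(3, len(cand) + 1):
        ts, ls = tt[-n:], lc[-n:]
        slope, intercept = np.polyfit(ts, ls, 1)
        pred = slope * ts + intercept
        ss_res = float(np.sum((ls - pred) ** 2))
        ss_tot = float(np.sum((ls - ls.mean()) ** 2))
        if ss_tot == 0:
            continue
        r2 = 1 - ss_res / ss_tot
        r2_adj = 1 - (1 - r2) * (n - 1) / (n - 2)
        if slope < 0 and r2_adj > best[2]:
            best = (-slope, n, r2_adj)
    lam, n, _ = best
    return lam, n


def nca(times: Sequence[float], concs: Sequence[float],
        dose_mg: Optional[float] = None, weight: Optional[float] = None) -> PKMetrics:
    """Non-compartmental analysis of one profile (times days, concs μg/mL).

    With fewer than 3 positive terminal points the half-life and AUC_0-inf
    are flagged not-estimable (None) and the remaining metrics returned.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(concs, dtype=float)
    if t.size < 3:
        raise DomainError("need at least 3 profile points")
    if np.any(np.diff(t) <= 0):
        raise DomainError("times must be strictly increasing")
    if np.any(c < 0):
        raise DomainError("concentrations must be >= 0")

    i_max = int(np.argmax(c))
    cmax, tmax = float(c[i_max]), float(t[i_max])
    auc_t = _auc_lin_up_log_down(t, c)

    lam, n_pts = _terminal_fit(t, c)
    if lam is None:
        return PKMetrics(cmax=cmax, tmax=tmax, auc_0_t=auc_t, auc_0_inf=None,
                         t_half=None, clearance=None)
    c_last = float(c[c > 0][-1]) if np.any(c > 0) else 0.0
    auc_inf = auc_t + c_last / lam
    t_half = float(np.log(2) / lam)
    cl = None
    if dose_mg is not None and weight is not None and auc_inf > 0:
        cl = dose_mg * 1000.0 / (auc_inf * weight)  # mL/day/kg
    return PKMetrics(cmax=cmax, tmax=tmax, auc_0_t=auc_t, auc_0_inf=float(auc_inf),
                     t_half=t_half, clearance=cl, lambda_z=float(lam),
                     n_lambda_points=n_pts)


def fold_error(observed: float, predicted: float) -> float:
    """Symmetric fold difference max(o/p, p/o) >= 1."""
    if observed <= 0 or predicted <= 0:
        raise DomainError("fold_error needs strictly positive inputs")
    return float(max(observed / predicted, predicted / observed))


def aafe(observed: Sequence[float], predicted: Sequence[float]) -> float:
    """Absolute average fold error, 10^(mean |log10(pred/obs)|)."""
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if o.shape != p.shape or o.ndim != 1:
        raise DomainError("observed and predicted must be equal-length vectors")
    if o.size == 0:
        raise DomainError("empty vectors")
    if np.any(o <= 0) or np.any(p <= 0):
        raise DomainError("aafe needs strictly positive values")
    return float(10 ** np.mean(np.abs(np.log10(p / o))))
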