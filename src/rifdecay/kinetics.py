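"""Per-transcript decay-rate and half-life estimation from chase series.

After rifampicin blocks transcription initiation, each mRNA's level follows
first-order decay, so ln intensity declines linearly with time at rate k and
t1/2 = ln2 / k.  The reliability of an estimate is judged by the coefficient
of variation of the fitted slope, cv = 100 x se(k)/k (percent): estimates
with cv outside (0, 40] — including every negative slope — are flagged
unreliable but retained.

An optional onset-delay model holds the level flat for tau minutes before
the exponential decline (residual elongation after the initiation block),
with continuity at tau; tau is chosen on a grid by least squares.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DecaySeries",
    "HalfLifeEstimate",
    "fit_exponential_decay",
    "fit_decay_with_delay",
    "fit_decay_matrix",
    "reliability_filter",
    "halflife_from_ct_slope",
    "intersect_reliable",
    "default_delay_grid",
]

LN2 = np.log(2.0)
CV_MAX_DEFAULT = 40.0


class InsufficientDataError(ValueError):
    """Too few points or distinct times to fit a decay model."""


@dataclass
class DecaySeries:
    """Post-rifampicin ln-intensity measurements for one gene in one
    condition, pooled over the replicate arrays."""

    gene_id: str
    condition: str
    times_min: np.ndarray
    ln_intensity: np.ndarray

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.ln_intensity = np.asarray(self.ln_intensity, dtype=float)
        if self.times_min.shape != self.ln_intensity.shape:
            raise ValueError("times and intensities must have equal length")
        if (self.times_min < 0).any():
            raise ValueError("times must be non-negative")


@dataclass
class HalfLifeEstimate:
    gene_id: str
    condition: str
    k_per_min: float  # decay constant, -slope of ln intensity vs time
    se_k: float
    cv_percent: float  # 100 x se_k / k; negative when k < 0
    halflife_min: float  # ln2 / k; negative when k < 0
    delay_min: float  # onset delay tau (0 for the no-delay model)
    r_squared: float
    n_points: int
    reliable: bool


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """Slope, se(slope), r^2 and RSS of y = a + b x by least squares."""
    n = x.size
    xm, ym = x.mean(), y.mean()
    dx = x - xm
    sxx = float(dx @ dx)
    if sxx == 0.0:
        raise InsufficientDataError("zero variance in time: cannot fit a slope")
    slope = float(dx @ (y - ym)) / sxx
    resid = y - ym - slope * dx
    rss = float(resid @ resid)
    sst = float((y - ym) @ (y - ym))
    r2 = 1.0 if sst == 0.0 else 1.0 - rss / sst
    se = np.sqrt(rss / (n - 2) / sxx) if n > 2 else np.nan
    return slope, se, r2, rss


def _estimate_from_slope(
    series: DecaySeries, slope: float, se: float, r2: float, delay: float, n: int
) -> HalfLifeEstimate:
    k = -slope
    with np.errstate(divide="ignore"):
        cv = 100.0 * se / k if k != 0.0 else np.inf
        halflife = LN2 / k if k != 0.0 else np.inf
    est = HalfLifeEstimate(
        gene_id=series.gene_id,
        condition=series.condition,
        k_per_min=k,
        se_k=se,
        cv_percent=cv,
        halflife_min=halflife,
        delay_min=delay,
        r_squared=r2,
        n_points=n,
        reliable=False,
    )
    return reliability_filter([est])[0]


def _check_series(series: DecaySeries) -> None:
    if series.times_min.size < 3 or np.unique(series.times_min).size < 3:
        raise InsufficientDataError(
            f"{series.gene_id}/{series.condition}: need >= 3 points at >= 3 "
            f"distinct times, got {series.times_min.size} points at "
            f"{np.unique(series.times_min).size} distinct times"
        )


def fit_exponential_decay(series: DecaySeries) -> HalfLifeEstimate:
    """OLS of ln intensity on time; k is the negated slope (per minute).

    A rising series yields k < 0, a negative half-life and a negative cv,
    and is always flagged unreliable.
    """
    _check_series(series)
    slope, se, r2, _ = _ols_line(series.times_min, series.ln_intensity)
    return _estimate_from_slope(series, slope, se, r2, 0.0, series.times_min.size)


def default_delay_grid(max_min: float = 3.0, step_min: float = 0.25) -> np.ndarray:
    return np.arange(0.0, max_min + step_min / 2, step_min)


def fit_decay_with_delay(
    series: DecaySeries, delay_grid: Sequence[float] | None = None
) -> HalfLifeEstimate:
    """Fit a flat-then-exponential model, choosing the onset delay on a grid.

    For each candidate tau the model ln I = c + b * max(0, t - tau) (flat at
    c up to tau, linear decline after, continuous at tau) is fit by least
    squares; the tau with the smallest residual sum of squares wins, ties
    broken toward smaller tau.  Candidates leaving fewer than 3 points after
    tau are skipped.
    """
    _check_series(series)
    t, y = series.times_min, series.ln_intensity
    if delay_grid is None:
        delay_grid = default_delay_grid()
    grid = np.sort(np.unique(np.asarray(delay_grid, dtype=float)))
    if (grid < 0).any() or (grid >= t.max()).any():
        raise ValueError("delay grid must lie within [0, max time)")

    best = None
    for tau in grid:
        after = t > tau
        if after.sum() < 3 or np.unique(t[after]).size < 2:
            continue
        u = np.maximum(0.0, t - tau)
        try:
            slope, se, r2, rss = _ols_line(u, y)
        except InsufficientDataError:
            continue
        if best is None or rss < best[0] - 1e-12:
            best = (rss, tau, slope, se, r2)
    if best is None:
        raise InsufficientDataError(
            f"{series.gene_id}/{series.condition}: no delay candidate leaves "
            ">= 3 points after onset"
        )
    _, tau, slope, se, r2 = best
    return _estimate_from_slope(series, slope, se, r2, float(tau), t.size)


def fit_decay_matrix(
    ln_matrix: pd.DataFrame,
    times_min: Sequence[float],
    condition: str,
    delay_grid: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Vectorized decay fits for every row of a genes x arrays ln matrix.

    ``times_min`` gives the chase time of each column.  With a
    ``delay_grid`` the flat-then-exponential model is fit (grid search shared
    across genes); otherwise the plain exponential model.  Returns one row
    per gene with the same fields as :class:`HalfLifeEstimate`.
    """
    t = np.asarray(times_min, dtype=float)
    y = ln_matrix.to_numpy(dtype=float)
    if y.shape[1] != t.size:
        raise ValueError("times_min length must match the number of arrays")
    if t.size < 3 or np.unique(t).size < 3:
        raise InsufficientDataError("need >= 3 arrays at >= 3 distinct times")

    grid = [0.0] if delay_grid is None else np.sort(np.unique(np.asarray(delay_grid, float)))
    best_rss = np.full(y.shape[0], np.inf)
    best = None
    for tau in grid:
        if (t > tau).sum() < 3 or np.unique(t[t > tau]).size < 2:
            continue
        u = np.maximum(0.0, t - tau)
        du = u - u.mean()
        sxx = float(du @ du)
        if sxx == 0.0:
            continue
        ym = y.mean(axis=1, keepdims=True)
        slope = (y - ym) @ du / sxx
        resid = y - ym - slope[:, None] * du[None, :]
        rss = np.einsum("ij,ij->i", resid, resid)
        sst = np.einsum("ij,ij->i", y - ym, y - ym)
        improved = rss < best_rss - 1e-12
        if best is None:
            se = np.sqrt(rss / (t.size - 2) / sxx)
            best = {
                "slope": slope.copy(),
                "se": se,
                "rss": rss.copy(),
                "sst": sst,
                "tau": np.full(y.shape[0], tau),
            }
            best_rss = rss.copy()
        elif improved.any():
            se = np.sqrt(rss / (t.size - 2) / sxx)
            for key, val in (("slope", slope), ("se", se), ("rss", rss), ("tau", tau)):
                if np.isscalar(val):
                    best[key][improved] = val
                else:
                    best[key][improved] = val[improved]
            best_rss[improved] = rss[improved]
    if best is None:
        raise InsufficientDataError("no delay candidate leaves >= 3 points after onset")

    k = -best["slope"]
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(k != 0.0, 100.0 * best["se"] / k, np.inf)
        halflife = np.where(k != 0.0, LN2 / k, np.inf)
        r2 = np.where(best["sst"] > 0.0, 1.0 - best["rss"] / best["sst"], 1.0)
    out = pd.DataFrame(
        {
            "condition": condition,
            "k_per_min": k,
            "se_k": best["se"],
            "cv_percent": cv,
            "halflife_min": halflife,
            "delay_min": best["tau"],
            "r_squared": r2,
            "n_points": t.size,
        },
        index=ln_matrix.index,
    )
    out["reliable"] = reliable_mask(out["cv_percent"], out["k_per_min"])
    return out


def reliable_mask(cv_percent, k_per_min, cv_max: float = CV_MAX_DEFAULT):
    """Reliability rule: k > 0 and finite cv within [0, cv_max].

    Negative cv (rising series) is unreliable; cv exactly 0 only occurs for
    a perfect noiseless fit, which is reliable.
    """
    cv = np.asarray(cv_percent, dtype=float)
    k = np.asarray(k_per_min, dtype=float)
    return np.isfinite(cv) & (cv >= 0.0) & (cv <= cv_max) & (k > 0.0)


def reliability_filter(
    estimates: Iterable[HalfLifeEstimate], cv_max: float = CV_MAX_DEFAULT
) -> list[HalfLifeEstimate]:
    """Set the reliable flag on every estimate; nothing is dropped."""
    out = []
    for est in estimates:
        ok = bool(reliable_mask(est.cv_percent, est.k_per_min, cv_max))
        out.append(replace(est, reliable=ok))
    return out


def halflife_from_ct_slope(slope_cycles_per_min: float) -> float:
    """RT-qPCR half-life: the reciprocal of the CT-vs-time slope.

    The threshold cycle rises by one per template halving, so a slope of s
    cycles/min means one halving every 1/s minutes.
    """
    if slope_cycles_per_min <= 0:
        raise ValueError(
            f"CT slope must be strictly positive (decaying mRNA), got {slope_cycles_per_min}"
        )
    return 1.0 / slope_cycles_per_min


def intersect_reliable(
    per_condition: Mapping[str, pd.DataFrame | Iterable[HalfLifeEstimate]],
) -> tuple[set[str], dict[str, int]]:
    """Genes reliable in every condition, plus per-condition reliable counts."""
    if not per_condition:
        raise ValueError("at least one condition required")
    sets: dict[str, set[str]] = {}
    for cond, est in per_condition.items():
        if isinstance(est, pd.DataFrame):
            sets[cond] = set(est.index[est["reliable"].astype(bool)])
        else:
            sets[cond] = {e.gene_id for e in est if e.reliable}
    counts = {c: len(s) for c, s in sets.items()}
    inter = set.intersection(*sets.values())
    return inter, counts
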