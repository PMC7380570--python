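"""Statistical comparisons: stability changes, differential expression,
multiple-testing correction and distribution-level rank tests.

Half-life changes between two conditions are tested through the interaction
term of a per-gene linear model ln I ~ condition + time + condition:time
(separate intercepts and slopes per condition); differential expression of
T0 concentrations uses an empirical-Bayes moderated t statistic in which
per-gene variances are shrunk toward a pooled prior estimated from the
ensemble of genes.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special, stats as sps
from statsmodels.stats.multitest import multipletests

from .kinetics import DecaySeries, InsufficientDataError, _ols_line

__all__ = [
    "stability_interaction_test",
    "stability_interaction_matrix",
    "adjust_pvalues",
    "moderated_t_test",
    "call_differential",
    "call_stability",
    "kruskal_wallis",
    "dunn_posthoc",
]

LN2 = np.log(2.0)


# ---------------------------------------------------------------------------
# stability comparison


def stability_interaction_test(
    series_a: DecaySeries, series_b: DecaySeries
) -> tuple[float, float]:
    """Test whether the decay slope differs between two conditions.

    Fits ln I = a_c + b_c t with separate intercept and slope per condition
    on the pooled points and returns the two-sided p-value of the slope
    difference (the time x condition interaction) together with
    log2(t1/2_B / t1/2_A) computed from the per-condition slopes.
    """
    for s in (series_a, series_b):
        if s.times_min.size < 3 or np.unique(s.times_min).size < 3:
            raise InsufficientDataError(
                f"{s.gene_id}/{s.condition}: need >= 3 points at >= 3 distinct times"
            )
    slope_a, _, _, rss_a = _ols_line(series_a.times_min, series_a.ln_intensity)
    slope_b, _, _, rss_b = _ols_line(series_b.times_min, series_b.ln_intensity)
    na, nb = series_a.times_min.size, series_b.times_min.size
    df = na + nb - 4  # two intercepts + two slopes
    if df <= 0:
        raise InsufficientDataError("not enough points for the interaction model")
    s2 = (rss_a + rss_b) / df
    sxx_a = float(((series_a.times_min - series_a.times_min.mean()) ** 2).sum())
    sxx_b = float(((series_b.times_min - series_b.times_min.mean()) ** 2).sum())
    se_diff = np.sqrt(s2 * (1.0 / sxx_a + 1.0 / sxx_b))
    tstat = (slope_b - slope_a) / se_diff if se_diff > 0 else np.inf * np.sign(slope_b - slope_a)
    p = 2.0 * sps.t.sf(abs(tstat), df) if np.isfinite(tstat) else 0.0
    if slope_b == slope_a:
        p = 1.0
    ka, kb = -slope_a, -slope_b
    log2fc = np.log2(ka / kb) if ka > 0 and kb > 0 else np.nan
    return float(log2fc), float(p)


def stability_interaction_matrix(
    ln_a: pd.DataFrame,
    times_a: Sequence[float],
    ln_b: pd.DataFrame,
    times_b: Sequence[float],
) -> pd.DataFrame:
    """Vectorized interaction test for every gene (row) of two ln matrices.

    Columns of each matrix are arrays sampled at ``times_a``/``times_b``.
    Returns log2_fc_halflife, p_value, and the per-condition slopes.
    """
    genes = ln_a.index
    if not genes.equals(ln_b.index):
        raise ValueError("the two matrices must share the same gene index")
    ta = np.asarray(times_a, float)
    tb = np.asarray(times_b, float)
    ya, yb = ln_a.to_numpy(float), ln_b.to_numpy(float)

    def _slopes(y, t):
        dt = t - t.mean()
        sxx = float(dt @ dt)
        slope = (y - y.mean(axis=1, keepdims=True)) @ dt / sxx
        resid = y - y.mean(axis=1, keepdims=True) - slope[:, None] * dt[None, :]
        return slope, np.einsum("ij,ij->i", resid, resid), sxx

    slope_a, rss_a, sxx_a = _slopes(ya, ta)
    slope_b, rss_b, sxx_b = _slopes(yb, tb)
    df = ta.size + tb.size - 4
    if df <= 0:
        raise InsufficientDataError("not enough arrays for the interaction model")
    s2 = (rss_a + rss_b) / df
    se = np.sqrt(s2 * (1.0 / sxx_a + 1.0 / sxx_b))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = (slope_b - slope_a) / se
        p = 2.0 * sps.t.sf(np.abs(tstat), df)
        log2fc = np.where(
            (slope_a < 0) & (slope_b < 0), np.log2(slope_a / slope_b), np.nan
        )
    p = np.where(slope_b == slope_a, 1.0, p)
    return pd.DataFrame(
        {
            "log2_fc_halflife": log2fc,
            "p_value": p,
            "slope_a": slope_a,
            "slope_b": slope_b,
        },
        index=genes,
    )


def call_stability(table: pd.DataFrame, alpha: float = 0.1, method: str = "BH") -> pd.DataFrame:
    """Adjust interaction p-values and classify each gene.

    stabilized: adj p < alpha and log2 half-life FC > 0; destabilized:
    adj p < alpha and FC < 0; otherwise unchanged.
    """
    out = table.copy()
    out["adj_p_value"] = adjust_pvalues(out["p_value"].to_numpy(), method=method)
    status = np.full(len(out), "unchanged", dtype=object)
    sig = out["adj_p_value"].to_numpy() < alpha
    fc = out["log2_fc_halflife"].to_numpy()
    status[sig & (fc > 0)] = "stabilized"
    status[sig & (fc < 0)] = "destabilized"
    out["status"] = status
    return out


# ---------------------------------------------------------------------------
# multiple testing


def adjust_pvalues(p_values, method: str = "BH") -> np.ndarray:
    """Benjamini-Hochberg step-up or Bonferroni adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1) | ~np.isfinite(p)).any():
        raise ValueError("p-values must lie in [0, 1]")
    key = {"BH": "fdr_bh", "bh": "fdr_bh", "bonferroni": "bonferroni"}.get(method)
    if key is None:
        raise ValueError(f"unknown adjustment method {method!r}")
    return multipletests(p, method=key)[1]


# ---------------------------------------------------------------------------
# differential expression


def _trigamma_inverse(y: float) -> float:
    # Newton iteration on trigamma(x) = y (decreasing, convex)
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def _fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of the scaled inverse chi-square prior
    (d0, s0^2) to the observed per-gene variances, via moments of ln s^2."""
    ok = s2 > 0
    if ok.sum() < 2:
        return np.inf, float(np.median(s2[ok])) if ok.any() else 0.0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - special.polygamma(1, df / 2.0)
    if evar <= 0:
        d0 = np.inf
        s0_2 = float(np.exp(emean))
    else:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_2 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_2


def moderated_t_test(
    log_a: pd.DataFrame | np.ndarray,
    log_b: pd.DataFrame | np.ndarray,
    d0: float | None = None,
    s0_squared: float | None = None,
) -> pd.DataFrame:
    """Empirical-Bayes moderated two-sample t test, gene by gene.

    Inputs are genes x replicates matrices of log2 concentrations.  Per-gene
    pooled variances s_g^2 (d_g df) are shrunk toward a prior (d0, s0^2)
    estimated by method of moments on ln s_g^2 across genes; the moderated
    statistic uses the posterior variance and d0 + d_g degrees of freedom.
    Passing ``d0=0`` reproduces the ordinary pooled t test.
    """
    idx = log_a.index if isinstance(log_a, pd.DataFrame) else None
    a = np.asarray(log_a, dtype=float)
    b = np.asarray(log_b, dtype=float)
    if a.ndim != 2 or b.ndim != 2 or a.shape[0] != b.shape[0]:
        raise ValueError("expected genes x replicates matrices with matching genes")
    na, nb = a.shape[1], b.shape[1]
    if na < 2 or nb < 2:
        raise ValueError("need >= 2 replicates per group")
    dg = na + nb - 2
    fc = b.mean(axis=1) - a.mean(axis=1)
    ssa = ((a - a.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    ssb = ((b - b.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    s2 = (ssa + ssb) / dg

    if d0 is None:
        d0, s0_fit = _fit_variance_prior(s2, dg)
        if s0_squared is None:
            s0_squared = s0_fit
    elif s0_squared is None:
        s0_squared = float(np.median(s2)) if d0 > 0 else 0.0

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_squared)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_squared + dg * s2) / (d0 + dg)
        df_total = d0 + dg

    denom = np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, fc / denom, np.where(fc == 0, 0.0, np.inf * np.sign(fc)))
    if np.isinf(df_total):
        p = 2.0 * sps.norm.sf(np.abs(t))
    else:
        p = 2.0 * sps.t.sf(np.abs(t), df_total)
    p = np.where((fc == 0), 1.0, p)

    out = pd.DataFrame({"log2_fc": fc, "t_statistic": t, "p_value": p, "s2_gene": s2})
    if idx is not None:
        out.index = idx
    out.attrs["d0"] = float(d0)
    out.attrs["s0_squared"] = float(s0_squared)
    return out


def call_differential(
    table: pd.DataFrame, alpha: float = 0.01, lfc: float = 1.0, method: str = "BH"
) -> pd.DataFrame:
    """Classify genes as up/down/none: adj p < alpha and |log2 FC| > lfc."""
    out = table.copy()
    if "adj_p_value" not in out.columns:
        out["adj_p_value"] = adjust_pvalues(out["p_value"].to_numpy(), method=method)
    status = np.full(len(out), "none", dtype=object)
    sig = out["adj_p_value"].to_numpy() < alpha
    fc = out["log2_fc"].to_numpy()
    status[sig & (fc > lfc)] = "up"
    status[sig & (fc < -lfc)] = "down"
    out["status"] = status
    return out


# ---------------------------------------------------------------------------
# distribution-level rank tests


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and its chi-square p-value."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("groups must be non-empty")
    flat = np.concatenate([np.asarray(g, float) for g in groups])
    if np.all(flat == flat[0]):
        return 0.0, 1.0
    h, p = sps.kruskal(*groups)
    return float(h), float(p)


def dunn_posthoc(
    groups: Sequence[Sequence[float]],
    labels: Sequence[str] | None = None,
    adjust: str = "BH",
) -> pd.DataFrame:
    """Dunn's pairwise z tests on joint ranks after a Kruskal-Wallis test.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j)) with
    tie correction T = sum(t^3 - t) / (12 (N - 1)); two-sided p-values are
    adjusted by the selected method.  Returns a symmetric matrix with 1 on
    the diagonal.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("groups must be non-empty")
    if labels is None:
        labels = [f"group{i + 1}" for i in range(len(arrays))]
    flat = np.concatenate(arrays)
    n_total = flat.size
    ranks = sps.rankdata(flat)
    sizes = np.array([a.size for a in arrays])
    bounds = np.cumsum(sizes)
    mean_ranks = [
        ranks[start:stop].mean()
        for start, stop in zip(np.r_[0, bounds[:-1]], bounds)
    ]
    _, tie_counts = np.unique(flat, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (12.0 * (n_total - 1)))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term

    m = len(arrays)
    pvals, ij = [], []
    for i in range(m):
        for j in range(i + 1, m):
            var = base_var * (1.0 / sizes[i] + 1.0 / sizes[j])
            if var <= 0:  # all values tied everywhere
                pvals.append(1.0)
            else:
                z = (mean_ranks[i] - mean_ranks[j]) / np.sqrt(var)
                pvals.append(2.0 * sps.norm.sf(abs(z)))
            ij.append((i, j))
    adjusted = adjust_pvalues(np.array(pvals), method=adjust)
    out = pd.DataFrame(np.eye(m), index=labels, columns=labels)
    for (i, j), p in zip(ij, adjusted):
        out.iat[i, j] = out.iat[j, i] = p
    np.fill_diagonal(out.to_numpy(), 1.0)
    out.iloc[:, :] = out.to_numpy()
    for i in range(m):
        out.iat[i, i] = 1.0
    return out
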