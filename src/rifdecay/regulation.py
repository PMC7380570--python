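"""Decomposition of mRNA concentration changes into degradational and
transcriptional control.

At steady state [RNA] = Vt / k (transcription rate over first-order decay
rate), so a concentration change between two conditions satisfies

    1 = dlnVt/dln[RNA] - dlnk/dln[RNA]

The degradational control coefficient rho_D = -dlnk/dln[RNA] measures the
share of the concentration change attributable to altered mRNA stability;
the transcriptional coefficient rho_T = dlnVt/dln[RNA] = 1 - rho_D the share
attributable to altered transcription.  Genes whose |dln[RNA]| or |dlnk|
falls in the lowest tail (default 5%) are excluded because the ratio is
numerically unstable for vanishing changes.  rho_D values are binned into
five regulatory categories from "transcriptional with opposing degradational
control" (rho_D < 0) to "degradational with opposing transcriptional
control" (rho_D > 1).
"""

from __future__ import annotations

import numbers

import numpy as np
import pandas as pd

__all__ = [
    "delta_logs",
    "regulation_coefficients",
    "exclusion_filter",
    "assign_category",
    "transcription_rate",
    "regulation_table",
]

CATEGORY_DESCRIPTIONS = {
    1: "mainly transcriptional control with opposite degradational control",
    2: "mainly transcriptional control with co-directional degradational control",
    3: "shared control",
    4: "mainly degradational control with co-directional transcriptional control",
    5: "mainly degradational control with opposite transcriptional control",
}


def _positive(x, name: str):
    x = np.asarray(x, dtype=float)
    if (x <= 0).any() or not np.isfinite(x).all():
        raise ValueError(f"{name} must be finite and strictly positive")
    return x


def delta_logs(conc_a, conc_b, k_a, k_b):
    """Two-point log differences: (ln(conc_B/conc_A), ln(k_B/k_A))."""
    conc_a = _positive(conc_a, "conc_a")
    conc_b = _positive(conc_b, "conc_b")
    k_a = _positive(k_a, "k_a")
    k_b = _positive(k_b, "k_b")
    return np.log(conc_b / conc_a), np.log(k_b / k_a)


def regulation_coefficients(dln_rna, dln_k):
    """rho_D = -dlnk/dln[RNA] and rho_T = 1 - rho_D.

    Scalar inputs with dln_rna == 0 raise; in arrays those genes get NaN
    (they are caught by :func:`exclusion_filter`).
    """
    scalar = isinstance(dln_rna, numbers.Number) and isinstance(dln_k, numbers.Number)
    dln_rna = np.asarray(dln_rna, dtype=float)
    dln_k = np.asarray(dln_k, dtype=float)
    if scalar and dln_rna == 0.0:
        raise ZeroDivisionError("dln_rna is zero: regulation coefficients undefined")
    with np.errstate(divide="ignore", invalid="ignore"):
        rho_d = np.where(dln_rna != 0.0, -dln_k / dln_rna, np.nan)
    rho_t = 1.0 - rho_d
    if scalar:
        return float(rho_d), float(rho_t)
    return rho_d, rho_t


def exclusion_filter(dln_rna, dln_k, fraction: float = 0.05) -> np.ndarray:
    """Mark genes in the lowest ``fraction`` of |dln[RNA]| or |dlnk|.

    The number excluded per criterion is round(fraction x n); ties at the
    boundary magnitude are all excluded.  The two exclusion sets are
    unioned.  Genes with dln_rna exactly 0 are always excluded (the
    coefficient is undefined there).
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    abs_rna = np.abs(np.asarray(dln_rna, dtype=float))
    abs_k = np.abs(np.asarray(dln_k, dtype=float))
    if abs_rna.shape != abs_k.shape:
        raise ValueError("dln_rna and dln_k must have equal length")
    n = abs_rna.size
    excluded = abs_rna == 0.0
    n_cut = int(round(fraction * n))
    if n_cut > 0:
        for mag in (abs_rna, abs_k):
            threshold = np.sort(mag)[n_cut - 1]
            excluded |= mag <= threshold
    return excluded


def assign_category(rho_d):
    """Map rho_D to regulatory category 1-5.

    1: rho_D < 0; 2: 0 <= rho_D < 0.4; 3: 0.4 <= rho_D <= 0.6 (shared
    control); 4: 0.6 < rho_D <= 1; 5: rho_D > 1.  Boundary values are
    resolved so rho_D = 0 is purely transcriptional (2) and rho_D = 1 purely
    degradational (4).
    """
    scalar = isinstance(rho_d, numbers.Number)
    x = np.asarray(rho_d, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("rho_d must be finite")
    cat = np.full(x.shape, 3, dtype=int)
    cat[x < 0.0] = 1
    cat[(x >= 0.0) & (x < 0.4)] = 2
    cat[(x > 0.6) & (x <= 1.0)] = 4
    cat[x > 1.0] = 5
    return int(cat) if scalar else cat


def transcription_rate(k_per_min, conc):
    """Steady-state transcription rate proxy Vt = k x [RNA]
    (concentration units per minute)."""
    k = _positive(k_per_min, "k_per_min")
    c = _positive(conc, "conc")
    out = k * c
    return float(out) if out.ndim == 0 else out


def regulation_table(
    conc_a: pd.Series,
    conc_b: pd.Series,
    k_a: pd.Series,
    k_b: pd.Series,
    exclude_fraction: float = 0.05,
) -> pd.DataFrame:
    """Full per-gene regulation decomposition for one condition pair.

    Inputs are aligned per-gene Series of T0 concentrations and decay
    constants in conditions A (upstream) and B (downstream).  Excluded genes
    (smallest-magnitude tail) keep their log differences but get no
    coefficients or category.
    """
    genes = conc_a.index
    for s, name in ((conc_b, "conc_b"), (k_a, "k_a"), (k_b, "k_b")):
        if not s.index.equals(genes):
            raise ValueError(f"{name} index does not match conc_a")
    dln_rna, dln_k = delta_logs(
        conc_a.to_numpy(), conc_b.to_numpy(), k_a.to_numpy(), k_b.to_numpy()
    )
    excluded = exclusion_filter(dln_rna, dln_k, fraction=exclude_fraction)
    rho_d, rho_t = regulation_coefficients(dln_rna, dln_k)
    rho_d = np.where(excluded, np.nan, rho_d)
    rho_t = np.where(excluded, np.nan, rho_t)
    category = np.full(len(genes), 0, dtype=int)
    ok = ~excluded
    category[ok] = assign_category(rho_d[ok])
    out = pd.DataFrame(
        {
            "dln_rna": dln_rna,
            "dln_k": dln_k,
            "rho_d": rho_d,
            "rho_t": rho_t,
            "vt_a": k_a.to_numpy() * conc_a.to_numpy(),
            "vt_b": k_b.to_numpy() * conc_b.to_numpy(),
            "category": category,  # 0 = excluded
            "excluded": excluded,
        },
        index=genes,
    )
    out.index.name = "gene_id"
    return out
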