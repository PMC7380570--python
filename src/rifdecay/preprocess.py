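"""Probe-level normalization and RMA-style summarization.

The chain mirrors standard one-color array processing: quantile
normalization across arrays of a replicate group, optional rescaling of
arrays to a common median over a shared ("invariant") probe set, two-way
median-polish summarization of each gene's probe block on the log2 scale,
and conversion of T0 intensities to concentrations via the total-RNA
extraction yield of each condition.

No background-correction model is applied: the synthetic generator produces
background-free intensities.  Real-data users should background-correct
upstream (a warning is logged on entry for real tables).
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "quantile_normalize",
    "scale_to_common_median",
    "median_polish_summarize",
    "median_polish_blocks",
    "summarize_probe_table",
    "to_concentration",
]


def quantile_normalize(matrix: pd.DataFrame | np.ndarray):
    """Force all columns (arrays) to share the same intensity distribution.

    Each column's order statistics are replaced by the across-column mean of
    order statistics; tied values within a column receive the reference value
    interpolated at their average rank, so ties stay tied.  Row identities
    are preserved.  A single-column input is returned unchanged with a
    warning.
    """
    is_frame = isinstance(matrix, pd.DataFrame)
    x = matrix.to_numpy(dtype=float) if is_frame else np.asarray(matrix, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a 2-D rows x arrays matrix")
    n, m = x.shape
    if m < 2:
        warnings.warn("quantile normalization needs >= 2 arrays; returning input unchanged")
        return matrix.copy() if is_frame else x.copy()
    reference = np.sort(x, axis=0).mean(axis=1)
    positions = np.arange(1, n + 1, dtype=float)
    out = np.empty_like(x)
    for j in range(m):
        ranks = rankdata(x[:, j], method="average")
        out[:, j] = np.interp(ranks, positions, reference)
    if is_frame:
        return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
    return out


def scale_to_common_median(
    matrix: pd.DataFrame, shared_probe_ids: Sequence | None = None
) -> tuple[pd.DataFrame, pd.Series]:
    """Rescale each array by one factor so medians over a shared probe set agree.

    The target is the grand median of the per-array medians computed on
    ``shared_probe_ids`` (default: all rows, i.e. the common probe set).
    Returns the scaled matrix and the per-array factors.  Rescaling by a
    single positive factor preserves within-array rank order.
    """
    if shared_probe_ids is None:
        shared = matrix
    else:
        shared_probe_ids = list(shared_probe_ids)
        if len(shared_probe_ids) == 0:
            raise ValueError("shared probe set is empty")
        missing = set(shared_probe_ids) - set(matrix.index)
        if missing:
            raise ValueError(f"shared probe(s) absent from matrix: {sorted(missing)[:5]}")
        shared = matrix.loc[shared_probe_ids]
    medians = shared.median(axis=0)
    if (medians <= 0).any():
        raise ValueError("non-positive per-array median; intensities must be positive")
    target = float(medians.median())
    factors = target / medians
    return matrix * factors, factors


def median_polish_summarize(
    block: pd.DataFrame | np.ndarray, max_iter: int = 20, tol: float = 1e-6
):
    """Summarize a probes x arrays block (log2 scale) into one value per array.

    Two-way median polish decomposes the block into overall + probe + array
    effects; the array summary is overall + array effect, which is robust to
    outlying probes.  Iteration stops when the largest absolute change of any
    effect falls below ``tol`` or after ``max_iter`` sweeps.
    """
    is_frame = isinstance(block, pd.DataFrame)
    x = block.to_numpy(dtype=float) if is_frame else np.asarray(block, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    if not np.isfinite(x).all():
        raise ValueError("median polish requires finite inputs")
    summary = _polish3d(x[None, :, :], max_iter=max_iter, tol=tol)[0]
    if is_frame:
        return pd.Series(summary, index=block.columns)
    return summary


def _polish3d(x: np.ndarray, max_iter: int = 20, tol: float = 1e-6) -> np.ndarray:
    """Median polish applied independently to every block of a (blocks,
    probes, arrays) stack; returns (blocks, arrays) summaries."""
    resid = x.astype(float).copy()
    nb, _, nc = resid.shape
    overall = np.zeros(nb)
    row = np.zeros(resid.shape[:2])
    col = np.zeros((nb, nc))
    for _ in range(max_iter):
        prev = col + overall[:, None]
        rdelta = np.median(resid, axis=2)
        resid -= rdelta[:, :, None]
        row += rdelta
        delta = np.median(col, axis=1)
        col -= delta[:, None]
        overall += delta
        cdelta = np.median(resid, axis=1)
        resid -= cdelta[:, None, :]
        col += cdelta
        delta = np.median(row, axis=1)
        row -= delta[:, None]
        overall += delta
        if np.max(np.abs(col + overall[:, None] - prev)) < tol:
            break
    return overall[:, None] + col


def median_polish_blocks(
    probe_matrix: pd.DataFrame, gene_of_probe: pd.Series, max_iter: int = 20, tol: float = 1e-6
) -> pd.DataFrame:
    """Summarize every gene's probe block of a probes x arrays log2 matrix.

    Genes whose probe count equals the modal count are polished as one
    vectorized stack; ragged genes fall back to per-block polish.
    """
    genes = gene_of_probe.loc[probe_matrix.index]
    counts = genes.value_counts()
    modal = counts.mode().iat[0]
    order = genes.groupby(genes, sort=True, observed=True).groups
    regular = [g for g, ix in order.items() if len(ix) == modal]
    ragged = [g for g, ix in order.items() if len(ix) != modal]

    out = {}
    if regular:
        stack = np.stack(
            [probe_matrix.loc[order[g]].to_numpy(dtype=float) for g in regular]
        )
        summaries = _polish3d(stack, max_iter=max_iter, tol=tol)
        for g, s in zip(regular, summaries):
            out[g] = s
    for g in ragged:
        out[g] = median_polish_summarize(
            probe_matrix.loc[order[g]], max_iter=max_iter, tol=tol
        ).to_numpy()
    result = pd.DataFrame.from_dict(out, orient="index", columns=probe_matrix.columns)
    result.index.name = "gene_id"
    return result.sort_index()


def summarize_probe_table(
    probe_table: pd.DataFrame,
    quantile_groups: Mapping[str, Sequence[str]] | None = None,
    median_scale: bool = False,
    max_iter: int = 20,
    tol: float = 1e-6,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Probe table -> (genes x arrays log2 expression matrix, array metadata).

    ``quantile_groups`` maps a group label to the array_ids to be quantile
    normalized together (arrays not listed are left as measured);
    ``median_scale`` applies common-median rescaling across all arrays before
    summarization.  Summarization is per-gene median polish on log2.
    """
    required = {"probe_id", "gene_id", "array_id", "intensity"}
    missing = required - set(probe_table.columns)
    if missing:
        raise ValueError(f"probe table missing column(s): {sorted(missing)}")
    wide = probe_table.pivot_table(
        index="probe_id", columns="array_id", values="intensity", observed=True
    )
    if wide.isna().any().any():
        raise ValueError("probe table is ragged: some probes missing on some arrays")
    wide.columns = wide.columns.astype(str)

    if quantile_groups:
        for _, arrays in quantile_groups.items():
            arrays = [a for a in map(str, arrays) if a in wide.columns]
            if len(arrays) >= 2:
                wide[arrays] = quantile_normalize(wide[arrays])
    if median_scale:
        wide, _ = scale_to_common_median(wide)

    gene_of_probe = (
        probe_table[["probe_id", "gene_id"]]
        .drop_duplicates()
        .set_index("probe_id")["gene_id"]
        .astype(str)
    )
    log2 = np.log2(wide)
    expression = median_polish_blocks(log2, gene_of_probe, max_iter=max_iter, tol=tol)

    meta_cols = [
        c
        for c in ("condition", "replicate", "minutes_after_rifampin")
        if c in probe_table.columns
    ]
    meta = (
        probe_table[["array_id", *meta_cols]]
        .drop_duplicates()
        .assign(array_id=lambda d: d["array_id"].astype(str))
        .set_index("array_id")
        .loc[expression.columns]
    )
    return expression, meta


def to_concentration(
    expression_t0: pd.DataFrame,
    array_condition: Mapping[str, str] | pd.Series,
    yields_ug_per_mgDW: Mapping[str, float],
) -> pd.DataFrame:
    """Convert T0 expression (log2) to concentrations in arbitrary units/mgDW.

    T0 replicate arrays of a condition are averaged on the intensity scale,
    then multiplied by that condition's total-RNA extraction yield.
    """
    array_condition = pd.Series(dict(array_condition) if not isinstance(array_condition, pd.Series) else array_condition)
    cols = [c for c in expression_t0.columns if c in array_condition.index]
    if len(cols) != expression_t0.shape[1]:
        unknown = set(expression_t0.columns) - set(array_condition.index)
        raise ValueError(f"arrays without condition assignment: {sorted(unknown)}")
    intensities = 2.0 ** expression_t0
    out = {}
    for cond in pd.unique(array_condition.loc[cols]):
        if cond not in yields_ug_per_mgDW:
            raise ValueError(f"missing extraction yield for condition {cond!r}")
        arrays = [a for a in cols if array_condition[a] == cond]
        out[cond] = intensities[arrays].mean(axis=1) * float(yields_ug_per_mgDW[cond])
    conc = pd.DataFrame(out)
    conc.index.name = "gene_id"
    return conc
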