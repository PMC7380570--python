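"""Synthetic rifampicin-chase experiments with known ground truth.

The generator emulates the reference study design: per-condition log-normal
half-life distributions, an onset delay before exponential decay (residual
transcription elongation after rifampicin blocks initiation), gene-specific
probe affinities, multiplicative measurement noise, and condition-specific
total-RNA extraction yields linking array intensities to concentrations.

Every downstream stage (summarization, decay fitting, stability comparison,
differential expression, regulation decomposition) can be tested against the
truth tables emitted here, without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import ConfigError, SimulationConfig

__all__ = ["GroundTruth", "generate_truth", "generate_decay_experiment", "generate_ct_series"]

LN2 = np.log(2.0)

PROBE_TABLE_COLUMNS = [
    "probe_id",
    "gene_id",
    "array_id",
    "condition",
    "replicate",
    "minutes_after_rifampin",
    "intensity",
]


@dataclass
class GroundTruth:
    """True per-gene parameters behind a simulated experiment.

    ``halflife_min``, ``delay_min`` and ``t0_concentration`` are genes x
    conditions frames; the pair-indexed frames hold, for each consecutive
    condition pair ``"A:B"``, the true log2 concentration fold change, the
    stabilization flag and the differential-expression label.
    """

    gene_ids: list[str]
    conditions: tuple[str, ...]
    halflife_min: pd.DataFrame
    delay_min: pd.DataFrame
    t0_concentration: pd.DataFrame  # arbitrary units / mgDW
    log2fc_concentration: pd.DataFrame
    stabilized: pd.DataFrame  # boolean
    de_status: pd.DataFrame  # {"up", "down", "none"}

    @property
    def decay_rate(self) -> pd.DataFrame:
        """First-order decay constants k = ln2 / t1/2, per minute."""
        return LN2 / self.halflife_min

    @property
    def pairs(self) -> list[str]:
        return list(self.log2fc_concentration.columns)

    def write(self, directory) -> None:
        """Write the truth tables as tab-delimited text keyed by gene_id."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, df in (
            ("true_halflife_min", self.halflife_min),
            ("true_delay_min", self.delay_min),
            ("true_t0_concentration", self.t0_concentration),
            ("true_log2fc_concentration", self.log2fc_concentration),
            ("true_stabilized", self.stabilized),
            ("true_de_status", self.de_status),
        ):
            df.to_csv(directory / f"{name}.tsv", sep="\t", index_label="gene_id")


def _median_correction(upstream_fractions, fold: float, log_sd: float) -> float:
    """Factor that restores the configured population median of a condition's
    half-life distribution after stabilization folds have been applied.

    By a given condition the half-life of a gene is median * exp(log_sd * Z)
    times ``fold`` for each earlier pair that selected it; the mixture over
    fold counts (independent selections) has a solvable population median.
    """
    from itertools import product

    from scipy.optimize import brentq
    from scipy.stats import norm

    fracs = [f for f in upstream_fractions]
    if not fracs or all(f == 0.0 for f in fracs):
        return 1.0
    if log_sd == 0.0:
        # degenerate spread: the mixture median is fold^j at the smallest j
        # with cumulative weight >= 0.5
        weights: dict[int, float] = {}
        for combo in product([0, 1], repeat=len(fracs)):
            w = 1.0
            for sel, f in zip(combo, fracs):
                w *= f if sel else 1.0 - f
            weights[sum(combo)] = weights.get(sum(combo), 0.0) + w
        acc = 0.0
        for j in sorted(weights):
            acc += weights[j]
            if acc >= 0.5:
                return fold**-j
        return 1.0

    def cdf_at(u: float) -> float:  # u = ln(m / configured median)
        total = 0.0
        for combo in product([0, 1], repeat=len(fracs)):
            w = 1.0
            for sel, f in zip(combo, fracs):
                w *= f if sel else 1.0 - f
            total += w * norm.cdf((u - sum(combo) * np.log(fold)) / log_sd)
        return total

    span = abs(np.log(fold)) * len(fracs) + 10.0 * log_sd
    u_med = brentq(lambda u: cdf_at(u) - 0.5, -span, span)
    return float(np.exp(-u_med))


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"g{i:0{width}d}" for i in range(n)]


def generate_truth(config: SimulationConfig) -> GroundTruth:
    """Draw the true half-lives, delays, concentrations and labels.

    Half-lives share one standard-normal quantile per gene across conditions,
    scaled to each condition's configured median, so that with identical
    medians and no stabilized genes every gene keeps the same half-life in
    every condition.  Stabilized genes get an extra ``stabilization_fold``
    multiplier from the downstream condition of their pair onward.
    Deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    conds = list(config.conditions)
    genes = _gene_ids(n)

    z = rng.standard_normal(n)
    medians = np.array([config.halflife_median_min[c] for c in conds])
    halflife = np.exp(config.halflife_log_sd * z)[:, None] * medians[None, :]

    pairs = config.condition_pairs
    pair_labels = [f"{a}:{b}" for a, b in pairs]
    stabilized = np.zeros((n, len(pairs)), dtype=bool)
    fracs = config.pair_stabilized_fractions
    for i, frac in enumerate(fracs):
        n_stab = int(round(frac * n))
        if n_stab == 0:
            continue
        idx = rng.choice(n, size=n_stab, replace=False)
        stabilized[idx, i] = True
        # persists: the fold applies to the downstream condition and onward,
        # so later consecutive pairs see no spurious (de)stabilization
        halflife[idx, i + 1 :] *= config.stabilization_fold
    # the extra folds inflate the distribution; rescale each condition so
    # its population median stays at the configured value
    for ci in range(len(conds)):
        factor = _median_correction(
            fracs[:ci], config.stabilization_fold, config.halflife_log_sd
        )
        halflife[:, ci] *= factor
    for i in range(len(pairs)):
        idx = stabilized[:, i]
        if idx.any() and np.any(halflife[idx, i + 1] <= halflife[idx, i]):
            raise ConfigError(
                "stabilization_fold: combined with the configured medians the "
                f"fold does not increase half-life across pair {pair_labels[i]}"
            )

    lo, hi = config.delay_range_min
    delay = rng.uniform(lo, hi, size=(n, len(conds)))

    base_conc = config.t0_concentration_scale * np.exp(
        config.concentration_log_sd * rng.standard_normal(n)
    )
    conc = np.tile(base_conc[:, None], (1, len(conds)))
    de_status = np.full((n, len(pairs)), "none", dtype=object)
    if config.transcription_mode == "constant_vt":
        # gene-constant transcription rate: [RNA] = Vt/k, so concentration
        # tracks half-life and concentration changes are purely degradational
        conc = conc * halflife / halflife[:, [0]]
    else:
        for i in range(len(pairs)):
            n_up = int(round(config.de_fraction_up * n))
            n_down = int(round(config.de_fraction_down * n))
            if n_up + n_down == 0:
                continue
            idx = rng.choice(n, size=n_up + n_down, replace=False)
            up, down = idx[:n_up], idx[n_up:]
            conc[up, i + 1 :] *= 2.0**config.de_effect_log2
            conc[down, i + 1 :] *= 2.0**-config.de_effect_log2

    log2fc = np.log2(conc[:, 1:] / conc[:, :-1]) if pairs else np.empty((n, 0))
    eps = 1e-9
    de_status[log2fc >= config.de_effect_log2 - eps] = "up"
    de_status[log2fc <= -config.de_effect_log2 + eps] = "down"

    idx = pd.Index(genes, name="gene_id")
    return GroundTruth(
        gene_ids=genes,
        conditions=tuple(conds),
        halflife_min=pd.DataFrame(halflife, index=idx, columns=conds),
        delay_min=pd.DataFrame(delay, index=idx, columns=conds),
        t0_concentration=pd.DataFrame(conc, index=idx, columns=conds),
        log2fc_concentration=pd.DataFrame(log2fc, index=idx, columns=pair_labels),
        stabilized=pd.DataFrame(stabilized, index=idx, columns=pair_labels),
        de_status=pd.DataFrame(de_status, index=idx, columns=pair_labels),
    )


def generate_decay_experiment(truth: GroundTruth, config: SimulationConfig) -> pd.DataFrame:
    """Simulate the probe-level intensity table for a rifampicin chase.

    For gene g in condition c the expected natural-log intensity of probe p
    at chase time t is::

        ln A_gc + ln affinity_gp            for t <= tau_gc
        ln A_gc + ln affinity_gp - k_gc (t - tau_gc)   for t > tau_gc

    where ``A_gc`` is the T0 intensity (true concentration divided by the
    condition's extraction yield) and ``tau`` the decay-onset delay.
    Gaussian noise of sd ``noise_log_sd`` is added on the ln scale.  One
    array is produced per (condition, replicate, time) of the design.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n, p = config.n_genes, config.probes_per_gene
    conds = list(config.conditions)

    ln_affinity = config.probe_affinity_log_sd * rng.standard_normal((n, p))
    probe_ids = np.array(
        [f"{g}_p{j:02d}" for g in truth.gene_ids for j in range(p)]
    )
    gene_col = np.repeat(np.array(truth.gene_ids), p)

    yields = {c: config.yields_ug_per_mgDW[c] for c in conds}
    frames: list[pd.DataFrame] = []
    for ci, c in enumerate(conds):
        ln_t0 = np.log(truth.t0_concentration[c].to_numpy() / yields[c])
        k = LN2 / truth.halflife_min[c].to_numpy()
        tau = truth.delay_min[c].to_numpy()
        for ri, times in enumerate(config.timepoints_per_replicate[c]):
            for t in times:
                t = float(t)
                ln_gene = ln_t0 - k * np.maximum(0.0, t - tau)
                ln_i = ln_gene[:, None] + ln_affinity
                if config.noise_log_sd > 0:
                    # weak signals are noisier: sd grows as the expected
                    # intensity approaches the scanner floor (capped — a
                    # probe far below the floor is pure noise either way)
                    sd = config.noise_log_sd * np.minimum(
                        1.0 + config.noise_floor_intensity / np.exp(ln_i), 20.0
                    )
                    ln_i = ln_i + sd * rng.standard_normal((n, p))
                label = f"{c}_r{ri + 1}_t{t:g}"
                frames.append(
                    pd.DataFrame(
                        {
                            "probe_id": probe_ids,
                            "gene_id": gene_col,
                            "array_id": label,
                            "condition": c,
                            "replicate": ri + 1,
                            "minutes_after_rifampin": t,
                            "intensity": np.exp(ln_i).ravel(),
                        }
                    )
                )
    table = pd.concat(frames, ignore_index=True)
    for col in ("probe_id", "gene_id", "array_id", "condition"):
        table[col] = table[col].astype("category")
    return table


def write_probe_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_probe_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = set(PROBE_TABLE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"probe table missing column(s): {sorted(missing)}")
    return table


def generate_ct_series(
    true_halflife_min: float,
    times,
    ct0: float = 20.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate an RT-qPCR threshold-cycle series under first-order decay.

    Template halves every ``true_halflife_min`` minutes, so the threshold
    cycle rises one cycle per half-life: ``CT(t) = ct0 + t / t1/2`` plus
    Gaussian noise in cycles.
    """
    if true_halflife_min <= 0:
        raise ValueError(f"true_halflife_min must be strictly positive, got {true_halflife_min}")
    times = np.asarray(times, dtype=float)
    ct = ct0 + times / true_halflife_min
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        ct = ct + noise_sd * rng.standard_normal(times.shape)
    return pd.DataFrame({"time_min": times, "ct": ct})
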