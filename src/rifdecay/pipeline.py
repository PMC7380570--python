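"""End-to-end orchestration: simulate -> preprocess -> fit -> compare ->
decompose, with a reproducible report.

All randomness flows from ``PipelineConfig.seed``: the pipeline copies it
into the simulation config, whose generator splits it internally (one
stream for the truth draw, one for the measurement noise), so any stage can
be re-run independently with identical results.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .kinetics import default_delay_grid, fit_decay_matrix, intersect_reliable
from .preprocess import summarize_probe_table, to_concentration
from .regulation import regulation_table
from .simulate import GroundTruth, generate_decay_experiment, generate_truth
from .stats import (
    call_differential,
    call_stability,
    moderated_t_test,
    stability_interaction_matrix,
)

__all__ = ["run_pipeline", "PipelineResult", "RunReport", "read_series_matrix", "write_series_matrix"]

LN2 = np.log(2.0)
log = logging.getLogger(__name__)


class SeriesMatrixParseError(ValueError):
    """Malformed series-matrix file; the message carries the line number."""


@dataclass
class RunReport:
    """Headline numbers of a run, all recomputable from the stage tables."""

    conditions: list[str]
    reliable_counts: dict[str, int]
    intersection_size: int
    median_halflife_min: dict[str, float]
    stabilized_counts: dict[str, int]
    destabilized_counts: dict[str, int]
    de_up_counts: dict[str, int]
    de_down_counts: dict[str, int]
    regulation_category_counts: dict[str, dict[int, int]]
    regulation_tested: dict[str, int]
    version: str = ""
    config_hash: str = ""
    seed: int = 0

    def to_text(self) -> str:
        lines = [
            f"rifdecay {self.version}  (config {self.config_hash}, seed {self.seed})",
            "",
            "Reliable half-life estimates per condition:",
        ]
        for c in self.conditions:
            lines.append(
                f"  {c}: {self.reliable_counts[c]} reliable, "
                f"median t1/2 = {self.median_halflife_min[c]:.2f} min"
            )
        lines.append(f"Genes reliable in every condition: {self.intersection_size}")
        lines.append("")
        for pair in self.stabilized_counts:
            lines.append(
                f"{pair}: {self.stabilized_counts[pair]} stabilized, "
                f"{self.destabilized_counts[pair]} destabilized; "
                f"DE {self.de_up_counts[pair]} up / {self.de_down_counts[pair]} down; "
                f"regulation on {self.regulation_tested[pair]} genes, "
                f"categories {dict(self.regulation_category_counts[pair])}"
            )
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.conditions:
            rows.append(
                {
                    "scope": c,
                    "metric": "reliable_count",
                    "value": self.reliable_counts[c],
                }
            )
            rows.append(
                {
                    "scope": c,
                    "metric": "median_halflife_min",
                    "value": self.median_halflife_min[c],
                }
            )
        rows.append({"scope": "all", "metric": "intersection_size", "value": self.intersection_size})
        for pair in self.stabilized_counts:
            rows.append({"scope": pair, "metric": "stabilized", "value": self.stabilized_counts[pair]})
            rows.append(
                {"scope": pair, "metric": "destabilized", "value": self.destabilized_counts[pair]}
            )
            rows.append({"scope": pair, "metric": "de_up", "value": self.de_up_counts[pair]})
            rows.append({"scope": pair, "metric": "de_down", "value": self.de_down_counts[pair]})
            rows.append(
                {"scope": pair, "metric": "regulation_tested", "value": self.regulation_tested[pair]}
            )
            for cat, n in self.regulation_category_counts[pair].items():
                rows.append({"scope": pair, "metric": f"category_{cat}", "value": n})
        return pd.DataFrame(rows)


@dataclass
class PipelineResult:
    config: PipelineConfig
    truth: GroundTruth
    expression: pd.DataFrame  # genes x arrays, log2
    array_meta: pd.DataFrame
    concentrations: pd.DataFrame  # genes x conditions, arbitrary units/mgDW
    halflife: pd.DataFrame  # long: one row per gene x condition
    reliable_intersection: set[str]
    stability: dict[str, pd.DataFrame] = field(default_factory=dict)
    differential_expression: dict[str, pd.DataFrame] = field(default_factory=dict)
    regulation: dict[str, pd.DataFrame] = field(default_factory=dict)
    report: RunReport | None = None


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage on a freshly simulated experiment.

    Stages: (1) draw ground truth and probe intensities; (2) summarize probe
    blocks to a log2 expression matrix (quantile-normalizing the T0
    replicate triplets when enabled) and convert T0 intensities to
    concentrations via the extraction yields; (3) fit per-gene decay rates
    per condition and apply the cv reliability filter; (4) test half-life
    changes (interaction model) and differential expression (moderated t)
    per consecutive condition pair; (5) decompose concentration changes of
    the eligible genes (differentially expressed AND reliable in every
    condition) into degradational/transcriptional control.
    """
    sim = replace(config.simulation, seed=config.seed)
    log.info(
        "thresholds: cv_max=%s stability_alpha=%s de_alpha=%s lfc=%s "
        "exclude_fraction=%s padjust=%s",
        config.cv_max,
        config.stability_alpha,
        config.de_alpha,
        config.lfc_threshold,
        config.exclude_fraction,
        config.padjust_method,
    )

    truth = generate_truth(sim)
    probes = generate_decay_experiment(truth, sim)

    # -- preprocessing ------------------------------------------------------
    t0_groups = None
    if config.quantile_normalize_t0:
        t0_groups = {
            c: [f"{c}_r{r + 1}_t0" for r in range(sim.replicates_per_condition)]
            for c in sim.conditions
        }
    expression, meta = summarize_probe_table(
        probes, quantile_groups=t0_groups, median_scale=config.median_scale_arrays
    )
    t0_arrays = meta.index[meta["minutes_after_rifampin"] == 0.0]
    concentrations = to_concentration(
        expression[list(t0_arrays)],
        meta.loc[t0_arrays, "condition"],
        sim.yields_ug_per_mgDW,
    )
    concentrations = concentrations[list(sim.conditions)]

    # -- decay fitting ------------------------------------------------------
    delay_grid = (
        default_delay_grid(config.delay_grid_max_min, config.delay_grid_step_min)
        if config.use_delay_model
        else None
    )
    per_condition: dict[str, pd.DataFrame] = {}
    ln_matrices: dict[str, tuple[pd.DataFrame, np.ndarray]] = {}
    for c in sim.conditions:
        arrays = meta.index[meta["condition"] == c]
        times = meta.loc[arrays, "minutes_after_rifampin"].to_numpy(float)
        ln_matrix = expression[list(arrays)] * LN2  # log2 -> natural log
        ln_matrices[c] = (ln_matrix, times)
        est = fit_decay_matrix(ln_matrix, times, condition=c, delay_grid=delay_grid)
        est["reliable"] &= est["cv_percent"] <= config.cv_max
        per_condition[c] = est
    halflife = pd.concat(per_condition.values()).rename_axis("gene_id").reset_index()
    intersection, reliable_counts = intersect_reliable(per_condition)

    # -- per-pair comparisons ----------------------------------------------
    stability: dict[str, pd.DataFrame] = {}
    de: dict[str, pd.DataFrame] = {}
    regulation: dict[str, pd.DataFrame] = {}
    inter_genes = sorted(intersection)
    for a, b in sim.condition_pairs:
        pair = f"{a}:{b}"
        ln_a, times_a = ln_matrices[a]
        ln_b, times_b = ln_matrices[b]
        stab = stability_interaction_matrix(
            ln_a.loc[inter_genes], times_a, ln_b.loc[inter_genes], times_b
        )
        stability[pair] = call_stability(
            stab, alpha=config.stability_alpha, method=config.padjust_method
        )

        t0_a = meta.index[(meta["condition"] == a) & (meta["minutes_after_rifampin"] == 0.0)]
        t0_b = meta.index[(meta["condition"] == b) & (meta["minutes_after_rifampin"] == 0.0)]
        log2_conc_a = expression[list(t0_a)] + np.log2(sim.yields_ug_per_mgDW[a])
        log2_conc_b = expression[list(t0_b)] + np.log2(sim.yields_ug_per_mgDW[b])
        det = moderated_t_test(log2_conc_a, log2_conc_b)
        de[pair] = call_differential(
            det, alpha=config.de_alpha, lfc=config.lfc_threshold, method=config.padjust_method
        )

        eligible = sorted(
            (set(de[pair].index[de[pair]["status"] != "none"]) & intersection)
        )
        eligible = [
            g
            for g in eligible
            if per_condition[a].loc[g, "k_per_min"] > 0
            and per_condition[b].loc[g, "k_per_min"] > 0
        ]
        if eligible:
            regulation[pair] = regulation_table(
                concentrations.loc[eligible, a],
                concentrations.loc[eligible, b],
                per_condition[a].loc[eligible, "k_per_min"],
                per_condition[b].loc[eligible, "k_per_min"],
                exclude_fraction=config.exclude_fraction,
            )
        else:
            regulation[pair] = pd.DataFrame(
                columns=[
                    "dln_rna",
                    "dln_k",
                    "rho_d",
                    "rho_t",
                    "vt_a",
                    "vt_b",
                    "category",
                    "excluded",
                ]
            ).rename_axis("gene_id")

    report = RunReport(
        conditions=list(sim.conditions),
        reliable_counts=reliable_counts,
        intersection_size=len(intersection),
        median_halflife_min={
            c: float(
                per_condition[c].loc[per_condition[c]["reliable"], "halflife_min"].median()
            )
            for c in sim.conditions
        },
        stabilized_counts={p: int((t["status"] == "stabilized").sum()) for p, t in stability.items()},
        destabilized_counts={
            p: int((t["status"] == "destabilized").sum()) for p, t in stability.items()
        },
        de_up_counts={p: int((t["status"] == "up").sum()) for p, t in de.items()},
        de_down_counts={p: int((t["status"] == "down").sum()) for p, t in de.items()},
        regulation_category_counts={
            p: {
                cat: int((t["category"] == cat).sum())
                for cat in (1, 2, 3, 4, 5)
            }
            for p, t in regulation.items()
        },
        regulation_tested={p: int((~t["excluded"]).sum()) if len(t) else 0 for p, t in regulation.items()},
        version=__version__,
        config_hash=config.config_hash(),
        seed=config.seed,
    )

    result = PipelineResult(
        config=config,
        truth=truth,
        expression=expression,
        array_meta=meta,
        concentrations=concentrations,
        halflife=halflife,
        reliable_intersection=intersection,
        stability=stability,
        differential_expression=de,
        regulation=regulation,
        report=report,
    )
    if config.outdir is not None:
        write_results(result, config.outdir)
    return result


def write_results(result: PipelineResult, outdir) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    result.config.to_yaml(out / "config.yaml")
    result.truth.write(out / "truth")
    result.expression.to_csv(out / "expression_log2.tsv", sep="\t", index_label="gene_id")
    result.array_meta.to_csv(out / "array_metadata.tsv", sep="\t", index_label="array_id")
    result.concentrations.to_csv(out / "concentrations.tsv", sep="\t", index_label="gene_id")
    result.halflife.to_csv(out / "halflife.tsv", sep="\t", index=False)
    for pair, table in result.stability.items():
        table.to_csv(out / f"stability_{pair.replace(':', '_vs_')}.tsv", sep="\t", index_label="gene_id")
    for pair, table in result.differential_expression.items():
        table.to_csv(out / f"de_{pair.replace(':', '_vs_')}.tsv", sep="\t", index_label="gene_id")
    for pair, table in result.regulation.items():
        table.to_csv(out / f"regulation_{pair.replace(':', '_vs_')}.tsv", sep="\t", index_label="gene_id")
    (out / "report.txt").write_text(result.report.to_text() + "\n")
    result.report.to_frame().to_csv(out / "report.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# series-matrix ingestion (GEO-style tab-delimited exports)


def read_series_matrix(path) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Read a tab-delimited series-matrix-style file.

    Header metadata lines are prefixed with ``!`` (``!Key<TAB>value...``);
    the table starts at the first unprefixed line, whose first column is the
    gene/probe identifier and remaining columns are samples.  Returns the
    genes x samples matrix and the metadata mapping.
    """
    metadata: dict[str, list[str]] = {}
    header: list[str] | None = None
    rows: list[list[str]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("!"):
                if header is not None:
                    raise SeriesMatrixParseError(
                        f"line {lineno}: metadata line after the data table began"
                    )
                key, *values = line[1:].split("\t")
                metadata.setdefault(key, []).extend(v.strip('"') for v in values)
                continue
            fields = line.split("\t")
            if header is None:
                if len(fields) < 2:
                    raise SeriesMatrixParseError(
                        f"line {lineno}: table header needs an ID column and >= 1 sample"
                    )
                header = [f.strip('"') for f in fields]
                continue
            if len(fields) != len(header):
                raise SeriesMatrixParseError(
                    f"line {lineno}: expected {len(header)} fields, got {len(fields)}"
                )
            rows.append([f.strip('"') for f in fields])
    if header is None:
        raise SeriesMatrixParseError("no table header found")
    frame = pd.DataFrame(rows, columns=header).set_index(header[0])
    frame.index.name = "gene_id"
    try:
        frame = frame.astype(float)
    except ValueError as exc:
        raise SeriesMatrixParseError(f"non-numeric expression value: {exc}") from exc
    return frame, metadata


def write_series_matrix(matrix: pd.DataFrame, path, metadata: dict | None = None) -> None:
    with open(path, "w") as fh:
        for key, values in (metadata or {}).items():
            if isinstance(values, str):
                values = [values]
            fh.write("!" + "\t".join([key, *map(str, values)]) + "\n")
        matrix.to_csv(fh, sep="\t", index_label=matrix.index.name or "gene_id")
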