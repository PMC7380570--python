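"""Configuration objects for simulation and pipeline runs.

The defaults encode the reference study design: four culture phases of an
*E. coli* glucose-acetate-starvation experiment (P1 exponential growth, P2
glucose exhaustion, P3 acetate consumption, P4 carbon starvation), three
biological replicates per phase, and twelve arrays per phase (three T0
arrays plus nine post-rifampicin time points laid out unevenly across
replicates).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import yaml

__all__ = [
    "ConfigError",
    "SimulationConfig",
    "PipelineConfig",
    "DEFAULT_CONDITIONS",
    "DEFAULT_TIMEPOINTS",
    "DEFAULT_HALFLIFE_MEDIANS",
    "DEFAULT_YIELDS",
]


class ConfigError(ValueError):
    """Invalid configuration; the message names the offending field."""


DEFAULT_CONDITIONS: tuple[str, ...] = ("P1", "P2", "P3", "P4")

# Minutes after rifampicin addition for each (condition, replicate) sampling
# series.  Every replicate includes the T0 array; each condition totals 12
# arrays (3 x T0 + 9 distinct chase time points).
DEFAULT_TIMEPOINTS: dict[str, tuple[tuple[float, ...], ...]] = {
    "P1": ((0.0, 0.5, 2.0, 5.0), (0.0, 1.0, 2.5, 3.0, 7.0), (0.0, 1.5, 4.0)),
    "P2": ((0.0, 1.5, 3.0, 7.0), (0.0, 0.5, 4.0, 11.0), (0.0, 1.0, 2.0, 5.0)),
    "P3": ((0.0, 0.5, 4.0, 7.0), (0.0, 1.5, 3.0, 11.0), (0.0, 1.0, 2.0, 5.0)),
    "P4": ((0.0, 1.0, 4.0, 11.0), (0.0, 1.5, 2.0, 7.0), (0.0, 0.5, 3.0, 5.0)),
}

# Median mRNA half-life (minutes) per phase and total-RNA extraction yield
# (ug RNA per mg cell dry weight) per phase.
DEFAULT_HALFLIFE_MEDIANS: dict[str, float] = {"P1": 3.1, "P2": 6.3, "P3": 8.3, "P4": 9.5}
DEFAULT_YIELDS: dict[str, float] = {"P1": 45.2, "P2": 33.6, "P3": 24.3, "P4": 27.0}


def _as_pair_fractions(value, n_pairs: int, name: str) -> tuple[float, ...]:
    if isinstance(value, (int, float)):
        fracs = (float(value),) * n_pairs
    else:
        fracs = tuple(float(v) for v in value)
        if len(fracs) < n_pairs:
            raise ConfigError(
                f"{name}: expected a scalar or >= one value per consecutive "
                f"condition pair ({n_pairs}), got {len(fracs)}"
            )
        # a longer sequence (e.g. the 4-condition default with a 2-condition
        # design) is truncated to the pairs that exist
        fracs = fracs[:n_pairs]
    for f in fracs:
        if not 0.0 <= f <= 1.0:
            raise ConfigError(f"{name}: fraction {f} outside [0, 1]")
    return fracs


@dataclass
class SimulationConfig:
    """Parameters of the synthetic rifampicin-chase microarray experiment.

    Half-lives are drawn log-normally per condition around
    ``halflife_median_min``; a per-pair fraction of genes receives an extra
    ``stabilization_fold`` increase in the downstream condition (persisting
    into later conditions).  Measurement noise is Gaussian on the natural-log
    intensity scale, i.e. multiplicative on intensities.
    """

    n_genes: int = 500
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    replicates_per_condition: int = 3
    # condition -> one tuple of sampling minutes per replicate
    timepoints_per_replicate: Mapping[str, Sequence[Sequence[float]]] = field(
        default_factory=lambda: dict(DEFAULT_TIMEPOINTS)
    )
    halflife_median_min: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_HALFLIFE_MEDIANS)
    )
    halflife_log_sd: float = 0.5
    # per consecutive condition pair (scalar broadcasts to every pair)
    stabilized_fraction: float | Sequence[float] = (0.1, 0.0, 0.0)
    stabilization_fold: float = 2.0
    de_fraction_up: float = 0.05
    de_fraction_down: float = 0.10
    de_effect_log2: float = 2.0
    delay_range_min: tuple[float, float] = (0.0, 0.5)
    noise_log_sd: float = 0.2
    # scanner-floor surrogate: the ln-scale noise sd of a probe is scaled by
    # (1 + noise_floor_intensity / expected intensity), so weak signals —
    # low-abundance transcripts and late chase time points — are noisier.
    # Set to 0 for homoscedastic ln-noise.
    noise_floor_intensity: float = 5.0
    probes_per_gene: int = 32
    probe_affinity_log_sd: float = 0.5
    yields_ug_per_mgDW: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_YIELDS))
    # baseline T0 concentration distribution (arbitrary units/mgDW, ln scale)
    t0_concentration_scale: float = 1000.0
    concentration_log_sd: float = 1.0
    # "independent": T0 concentrations set independently of decay rates;
    # "constant_vt": concentration = Vt/k with a gene-constant transcription
    # rate, so concentration changes are driven purely by stability changes.
    transcription_mode: str = "independent"
    seed: int = 0

    def __post_init__(self) -> None:
        self.conditions = tuple(self.conditions)
        self.validate()

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ConfigError(f"n_genes: must be positive, got {self.n_genes}")
        if len(self.conditions) < 1:
            raise ConfigError("conditions: at least one condition required")
        if self.replicates_per_condition <= 0:
            raise ConfigError(
                f"replicates_per_condition: must be positive, got {self.replicates_per_condition}"
            )
        if self.probes_per_gene <= 0:
            raise ConfigError(f"probes_per_gene: must be positive, got {self.probes_per_gene}")
        for name in (
            "halflife_log_sd",
            "noise_log_sd",
            "probe_affinity_log_sd",
            "concentration_log_sd",
            "noise_floor_intensity",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name}: must be non-negative")
        for name in ("stabilization_fold", "de_effect_log2", "t0_concentration_scale"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name}: must be strictly positive")
        for name in ("de_fraction_up", "de_fraction_down"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}: fraction {v} outside [0, 1]")
        if self.de_fraction_up + self.de_fraction_down > 1.0:
            raise ConfigError("de_fraction_up + de_fraction_down exceeds 1")
        lo, hi = self.delay_range_min
        if lo < 0 or hi < lo:
            raise ConfigError(f"delay_range_min: invalid interval ({lo}, {hi})")
        if self.transcription_mode not in ("independent", "constant_vt"):
            raise ConfigError(
                f"transcription_mode: {self.transcription_mode!r} not in "
                "('independent', 'constant_vt')"
            )
        for c in self.conditions:
            if c not in self.halflife_median_min:
                raise ConfigError(f"halflife_median_min: missing condition {c!r}")
            if self.halflife_median_min[c] <= 0:
                raise ConfigError(f"halflife_median_min[{c!r}]: must be strictly positive")
            if c not in self.yields_ug_per_mgDW:
                raise ConfigError(f"yields_ug_per_mgDW: missing condition {c!r}")
            if self.yields_ug_per_mgDW[c] <= 0:
                raise ConfigError(f"yields_ug_per_mgDW[{c!r}]: must be strictly positive")
            if c not in self.timepoints_per_replicate:
                raise ConfigError(f"timepoints_per_replicate: missing condition {c!r}")
            reps = self.timepoints_per_replicate[c]
            if len(reps) != self.replicates_per_condition:
                raise ConfigError(
                    f"timepoints_per_replicate[{c!r}]: {len(reps)} replicate series, "
                    f"expected {self.replicates_per_condition}"
                )
            for i, series in enumerate(reps):
                if 0.0 not in [float(t) for t in series]:
                    raise ConfigError(
                        f"timepoints_per_replicate[{c!r}] replicate {i + 1}: "
                        "must include the T0 array (time 0)"
                    )
                if any(t < 0 for t in series):
                    raise ConfigError(
                        f"timepoints_per_replicate[{c!r}] replicate {i + 1}: negative time"
                    )
        # pre-resolve per-pair fractions so downstream code never re-validates
        self.pair_stabilized_fractions  # noqa: B018

    @property
    def condition_pairs(self) -> list[tuple[str, str]]:
        """Consecutive (upstream, downstream) condition pairs."""
        return [
            (self.conditions[i], self.conditions[i + 1])
            for i in range(len(self.conditions) - 1)
        ]

    @property
    def pair_stabilized_fractions(self) -> tuple[float, ...]:
        return _as_pair_fractions(
            self.stabilized_fraction, max(len(self.conditions) - 1, 0), "stabilized_fraction"
        )

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["timepoints_per_replicate"] = {
            c: [list(map(float, s)) for s in reps]
            for c, reps in self.timepoints_per_replicate.items()
        }
        d["conditions"] = list(self.conditions)
        d["delay_range_min"] = list(self.delay_range_min)
        if not isinstance(d["stabilized_fraction"], (int, float)):
            d["stabilized_fraction"] = list(self.pair_stabilized_fractions)
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        if "delay_range_min" in d:
            d["delay_range_min"] = tuple(d["delay_range_min"])
        if "conditions" in d:
            d["conditions"] = tuple(d["conditions"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown configuration field(s): {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class PipelineConfig:
    """End-to-end run settings: simulation, thresholds, normalization switches."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    cv_max: float = 40.0  # percent; reliability window is (0, cv_max]
    stability_alpha: float = 0.1
    de_alpha: float = 0.01
    lfc_threshold: float = 1.0  # |log2 FC| must exceed this for a DE call
    exclude_fraction: float = 0.05
    padjust_method: str = "BH"  # or "bonferroni"
    # normalization switches (see docs: synthetic arrays share a common scale)
    quantile_normalize_t0: bool = True
    median_scale_arrays: bool = False
    use_delay_model: bool = False
    delay_grid_max_min: float = 3.0
    delay_grid_step_min: float = 0.25
    outdir: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.cv_max:
            raise ConfigError("cv_max: must be strictly positive")
        for name in ("stability_alpha", "de_alpha"):
            if not 0 < getattr(self, name) < 1:
                raise ConfigError(f"{name}: must be in (0, 1)")
        if self.lfc_threshold < 0:
            raise ConfigError("lfc_threshold: must be non-negative")
        if not 0 < self.exclude_fraction < 1:
            raise ConfigError("exclude_fraction: must be in (0, 1)")
        if self.padjust_method not in ("BH", "bonferroni"):
            raise ConfigError("padjust_method: must be 'BH' or 'bonferroni'")
        if self.delay_grid_step_min <= 0 or self.delay_grid_max_min < 0:
            raise ConfigError("delay grid: step must be positive, max non-negative")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulation"] = self.simulation.to_dict()
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        d = dict(d)
        sim = d.pop("simulation", {})
        if isinstance(sim, Mapping):
            sim = SimulationConfig.from_dict(sim)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown configuration field(s): {sorted(unknown)}")
        return cls(simulation=sim, **d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        """Stable hash of every threshold, switch and seed in the run.

        The output directory is not part of the hash: relocating a run does
        not change what was computed.
        """
        d = self.to_dict()
        d.pop("outdir", None)
        payload = json.dumps(d, sort_keys=True, default=float)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]
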