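import numpy as np
import pytest

from rifdecay import SimulationConfig, generate_decay_experiment, generate_truth
from rifdecay.kinetics import fit_decay_matrix
from rifdecay.preprocess import summarize_probe_table

LN2 = np.log(2.0)


@pytest.fixture(scope="session")
def small_config():
    """A fast two-condition design reused across tests."""
    return SimulationConfig(
        n_genes=60,
        conditions=("P1", "P2"),
        halflife_median_min={"P1": 3.1, "P2": 6.3},
        yields_ug_per_mgDW={"P1": 45.2, "P2": 33.6},
        timepoints_per_replicate={
            "P1": ((0.0, 0.5, 2.0, 5.0), (0.0, 1.0, 2.5, 3.0, 7.0), (0.0, 1.5, 4.0)),
            "P2": ((0.0, 1.5, 3.0, 7.0), (0.0, 0.5, 4.0, 11.0), (0.0, 1.0, 2.0, 5.0)),
        },
        probes_per_gene=8,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_truth(small_config):
    return generate_truth(small_config)


@pytest.fixture(scope="session")
def small_experiment(small_config, small_truth):
    return generate_decay_experiment(small_truth, small_config)


def summarize_and_fit(config, probes, delay_grid=None):
    """Probe table -> per-condition half-life estimate frames."""
    expr, meta = summarize_probe_table(probes)
    out = {}
    for c in config.conditions:
        arrays = meta.index[meta["condition"] == c]
        times = meta.loc[arrays, "minutes_after_rifampin"].to_numpy(float)
        out[c] = fit_decay_matrix(
            expr[list(arrays)] * LN2, times, condition=c, delay_grid=delay_grid
        )
    return out, expr, meta
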