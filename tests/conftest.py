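"""Shared fixtures: the standard synthetic benchmark and one trained model.

The benchmark is the fixed study condition used across the suite: 8 cell
types x 500 cells, 30 disjoint 10-gene terms over 400 genes, one active
term per type at log-fold ln 4, NB dispersion 2, two inert batch labels.
"""

import numpy as np
import pytest

import termvae as tv
from termvae.synthetic import benchmark_model_config

BENCH_SEED = 1


@pytest.fixture(scope="session")
def bench_termset():
    return tv.benchmark_termset(seed=BENCH_SEED)


@pytest.fixture(scope="session")
def bench_data(bench_termset):
    dataset, truth = tv.simulate_cells(
        bench_termset, tv.benchmark_config(bench_termset, cells_per_type=500, seed=BENCH_SEED)
    )
    return dataset, truth


@pytest.fixture(scope="session")
def bench_training(bench_termset, bench_data):
    """Train once on the benchmark, recording per-epoch mask violations."""
    dataset, _ = bench_data
    violations = []

    def record(epoch, state):
        off = np.abs(state.params["W_dec"] * (1 - state.mask)).max(initial=0.0)
        on = np.abs(state.params["W_soft"] * state.mask).max(initial=0.0)
        violations.append((epoch, off, on))

    state = tv.train(
        dataset, bench_termset, benchmark_model_config(seed=BENCH_SEED),
        epoch_callback=record,
    )
    return state, violations


@pytest.fixture(scope="session")
def bench_state(bench_training):
    return bench_training[0]


@pytest.fixture(scope="session")
def bench_scores(bench_state, bench_data):
    return tv.influence_scores(bench_state, bench_data[0])


@pytest.fixture(scope="session")
def bench_enrichment(bench_scores, bench_data):
    dataset, _ = bench_data
    return tv.enrichment(bench_scores, dataset.cell_types, seed=BENCH_SEED)


@pytest.fixture(scope="session")
def tiny_problem():
    """A 2-type, 6-term problem small enough for second-scale training."""
    termset = tv.simulate_termset(6, 5, 60, overlap_fraction=0.0, seed=9)
    import pandas as pd

    cell_types = ["alpha", "beta"]
    activity = pd.DataFrame(0.0, index=cell_types, columns=termset.term_ids)
    activity.loc["alpha", termset.term_ids[0]] = np.log(4)
    activity.loc["beta", termset.term_ids[1]] = np.log(4)
    config = tv.SimulationConfig(
        cell_types=cell_types,
        n_cells_per_type=60,
        n_genes=60,
        activity=activity,
        conditions=["c1", "c2"],
        dispersion=2.0,
        seed=9,
    )
    dataset, truth = tv.simulate_cells(termset, config)
    return termset, dataset, truth


@pytest.fixture(scope="session")
def tiny_state(tiny_problem):
    termset, dataset, _ = tiny_problem
    cfg = tv.ModelConfig(
        n_hidden=32, n_encoder_layers=2, max_epochs=15, patience=15,
        batch_size=32, seed=9,
    )
    return tv.train(dataset, termset, cfg)
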