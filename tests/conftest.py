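"""Shared fixtures: toy graphs, the desk-scale dataset, and training runs.

Everything is generated programmatically at test time; the expensive fixtures
(dataset, hierarchy, the batch of training runs) are session-scoped so the
acceptance tests share one copy.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from gpcn.hierarchy import build_hierarchy, desk_scale_hierarchy
from gpcn.models import GPCNModel, MemberSpec
from gpcn.tube_graphs import Graph, TubeSpec, build_tube_graph

TRAIN_SEEDS = (42, 43, 44)
TRAIN_EPOCHS = 160
WIDTH_SCALE = 0.25


def random_graph(rng: np.random.Generator, n: int, p: float = 0.5) -> Graph:
    """Connected Erdos-Renyi-ish graph: random edges plus a spanning path."""
    edges = {(i, i + 1) for i in range(n - 1)}
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                edges.add((i, j))
    return Graph(n, [(i, j, 1.0) for i, j in sorted(edges)])


@pytest.fixture(scope="session")
def toy_hierarchy():
    """12-node / 6-node tube pair with optimized prolongation."""
    return build_hierarchy(
        [build_tube_graph(TubeSpec(4, 3, 0)), build_tube_graph(TubeSpec(2, 3, 0))],
        max_iter=300,
    )


@pytest.fixture(scope="session")
def toy_gpcn(toy_hierarchy):
    specs = [MemberSpec(0, (4, 4), (8, 1)), MemberSpec(1, (5, 5), (8, 1))]
    return GPCNModel(toy_hierarchy, specs, in_features=3, rng=np.random.default_rng(7))


@pytest.fixture(scope="session")
def desk_data():
    """Desk-scale simulated dataset: 12-ring tube, 2 values per strength."""
    from gpcn.mt_simulator import desk_dataset

    return desk_dataset(seed=1)


@pytest.fixture(scope="session")
def desk_hierarchy():
    return desk_scale_hierarchy(max_iter=300)


@pytest.fixture(scope="session")
def desk_splits(desk_data):
    from gpcn.training import normalize, split_frames

    tr, va = split_frames(desk_data.n_frames, 0.1, seed=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # clamped-node positions are constant
        Xn, yn, stats = normalize(desk_data.X, desk_data.y, tr)
    return Xn[tr], yn[tr], Xn[va], yn[va], stats


@pytest.fixture(scope="session")
def training_runs(desk_hierarchy, desk_splits):
    """Histories of every (model/schedule, seed) combination under comparison."""
    from gpcn.presets import build_preset
    from gpcn.training import ScheduleSpec, TrainConfig, train

    Xtr, ytr, Xva, yva, _ = desk_splits
    jobs = {
        "single": ("Single GCN", ScheduleSpec("joint")),
        "gpcn": ("3-level GPCN", ScheduleSpec("joint")),
        "agpcn": ("3-level A-GPCN", ScheduleSpec("joint")),
        "agpcn_gamma2": ("3-level A-GPCN", ScheduleSpec("mu_cycle", gamma=2)),
        "agpcn_gamma3": ("3-level A-GPCN", ScheduleSpec("mu_cycle", gamma=3)),
    }
    runs: dict[tuple[str, int], object] = {}
    for label, (preset, sched) in jobs.items():
        for seed in TRAIN_SEEDS:
            model = build_preset(
                preset, desk_hierarchy, in_features=10,
                width_scale=WIDTH_SCALE, rng=np.random.default_rng(seed),
            )
            runs[(label, seed)] = train(
                model, Xtr, ytr, Xva, yva,
                TrainConfig(epochs=TRAIN_EPOCHS, seed=seed), sched,
            )
    return runs
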