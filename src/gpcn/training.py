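"""Normalization, losses, FLOP accounting, and multigrid training schedules.

Training minimizes fine-scale mean squared error with Adam (default
hyperparameters), batches of 8, 20 batches per epoch.  Inputs and targets are
standardized per (node, feature) over the training frames only; the reported
validation metric is the normalized MSE (NMSE), i.e. plain MSE in the
standardized target space.

Computational cost is tracked with the printed cost model: a GCN layer with
``n x n`` structure matrix Z (``|Z|`` nonzeros), ``n x F`` input and ``F x C``
filters costs ``n F (|Z| + C)``; a node-wise dense layer costs ``n F C``; a
projection (``n x k`` by ``k x m``) costs ``n m k``.  A training event is
charged the full-ensemble forward plus a backward pass over the event's
trainable levels only, with backward approximated at the same formula cost as
the corresponding forward pieces — this is what makes coarse-level smoothing
epochs cheaper than joint epochs.

Schedules: ``joint`` (every level, every epoch), multigrid ``mu_cycle`` with
recursion parameter gamma (gamma=1 is a V-cycle: fine, mid, coarse, mid,
fine), and ``coarse_to_fine`` (phases coarse, coarse+mid, all; each advanced
after 10 epochs without validation improvement).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import autodiff as ad
from .autodiff import Var
from .models import DiffPoolModel, EnsembleModel, GPCNModel, Member, NGCNModel

__all__ = [
    "TrainConfig",
    "NormStats",
    "ScheduleSpec",
    "FlopLedger",
    "normalize",
    "nmse",
    "flops_gcn_layer",
    "flops_dense",
    "flops_matmul",
    "schedule_sequence",
    "train",
    "split_frames",
    "model_flops",
    "flops_to_reach",
]


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 8
    epochs: int = 1000
    batches_per_epoch: int = 20
    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-7
    seed: int = 0
    validation_fraction: float = 0.1

    def __post_init__(self):
        if min(self.batch_size, self.epochs, self.batches_per_epoch) < 1:
            raise ValueError("counts must be positive")


@dataclass
class NormStats:
    """Per-(node, feature) standardization statistics from the training split."""

    x_mean: np.ndarray
    x_std: np.ndarray
    y_mean: np.ndarray
    y_std: np.ndarray

    def apply_x(self, X: np.ndarray) -> np.ndarray:
        return (X - self.x_mean) / self.x_std

    def apply_y(self, y: np.ndarray) -> np.ndarray:
        return (y - self.y_mean) / self.y_std

    def invert_x(self, X: np.ndarray) -> np.ndarray:
        return X * self.x_std + self.x_mean

    def invert_y(self, y: np.ndarray) -> np.ndarray:
        return y * self.y_std + self.y_mean


def split_frames(
    n_frames: int, validation_fraction: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Random train/validation split over frames, deterministic in the seed."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_frames)
    n_val = max(1, int(round(validation_fraction * n_frames)))
    return np.sort(perm[n_val:]), np.sort(perm[:n_val])


def normalize(
    X: np.ndarray,
    y: np.ndarray,
    train_idx: np.ndarray,
    stats: NormStats | None = None,
    std_floor: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray, NormStats]:
    """Standardize inputs and targets with training-split statistics.

    Statistics are taken over the first (frame) axis of the training tensors
    and applied to every frame; constant features get their std floored.
    """
    if stats is None:
        xt, yt = X[train_idx], y[train_idx]
        x_std, y_std = xt.std(axis=0), yt.std(axis=0)
        if np.any(x_std < std_floor) or np.any(y_std < std_floor):
            warnings.warn("constant feature encountered; flooring std", stacklevel=2)
        stats = NormStats(
            x_mean=xt.mean(axis=0),
            x_std=np.maximum(x_std, std_floor),
            y_mean=yt.mean(axis=0),
            y_std=np.maximum(y_std, std_floor),
        )
    return stats.apply_x(X), stats.apply_y(y), stats


def nmse(pred: np.ndarray, target: np.ndarray) -> float:
    """Mean squared error in standardized target space, over nodes and frames."""
    pred, target = np.asarray(pred), np.asarray(target)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {target.shape}")
    return float(np.mean((pred - target) ** 2))


# ---------------------------------------------------------------------------
# FLOP cost model
# ---------------------------------------------------------------------------


def flops_gcn_layer(n: int, F: int, nnz_Z: int, C: int) -> int:
    """Cost of one GCN layer: n F (|Z| + C)."""
    return int(n) * int(F) * (int(nnz_Z) + int(C))


def flops_dense(n: int, F: int, C: int) -> int:
    """Cost of a node-wise dense layer: n F C."""
    return int(n) * int(F) * int(C)


def flops_matmul(n: int, m: int, k: int) -> int:
    """Cost of an (n x k) by (k x m) product: n m k."""
    return int(n) * int(m) * int(k)


@dataclass
class FlopLedger:
    events: list[tuple[str, int]] = field(default_factory=list)

    def add(self, label: str, flops: int) -> None:
        if flops < 0:
            raise ValueError("negative FLOP count")
        self.events.append((label, int(flops)))

    @property
    def total(self) -> int:
        return sum(f for _, f in self.events)


def _member_flops(n: int, nnz: int, in_features: int, member: Member,
                  ledger: FlopLedger | None = None, tag: str = "") -> int:
    total = 0
    F = in_features
    for C in member.spec.gcn_filters:
        fl = flops_gcn_layer(n, F, nnz, C)
        total += fl
        if ledger is not None:
            ledger.add(f"{tag}gcn({F}->{C})", fl)
        F = C
    F = sum(member.spec.gcn_filters)
    for C in member.spec.dense_filters:
        fl = flops_dense(n, F, C)
        total += fl
        if ledger is not None:
            ledger.add(f"{tag}dense({F}->{C})", fl)
        F = C
    return total


def _nnz(Z) -> int:
    arr = Z.value if isinstance(Z, Var) else np.asarray(Z)
    return int(np.count_nonzero(arr))


def model_flops(model, in_features: int, ledger: FlopLedger | None = None) -> list[int]:
    """Per-level forward cost of one sample, under the printed cost model.

    Returns one entry per level: the cost of that level's member plus its
    restriction/prolongation products.  ``sum(model_flops(...))`` is the full
    forward cost.
    """
    per_level: list[int] = []
    if isinstance(model, GPCNModel):
        n_fine = model.structure_matrices[0].shape[0]
        for i, member in enumerate(model.members):
            n = model.structure_matrices[i].shape[0]
            fl = _member_flops(n, _nnz(model.structure_matrices[i]), in_features,
                               member, ledger, f"level{i}.")
            if i >= 1:  # P^T X down, P y up
                down = flops_matmul(n, in_features, n_fine)
                up = flops_matmul(n_fine, 1, n)
                fl += down + up
                if ledger is not None:
                    ledger.add(f"level{i}.restrict", down)
                    ledger.add(f"level{i}.prolong", up)
            per_level.append(fl)
    elif isinstance(model, NGCNModel):
        n = model.Z.shape[0]
        for Zr, member in zip(model.Z_powers, model.members):
            per_level.append(_member_flops(n, _nnz(Zr), in_features, member, ledger))
    elif isinstance(model, EnsembleModel):
        n, nnz = model.Z.shape[0], _nnz(model.Z)
        for member in model.members:
            per_level.append(_member_flops(n, nnz, in_features, member, ledger))
    elif isinstance(model, DiffPoolModel):
        n_prev, nnz_prev = model.Z.shape[0], _nnz(model.Z)
        n_fine = n_prev
        per_level.append(
            _member_flops(n_prev, nnz_prev, in_features, model.members[0], ledger, "level0.")
        )
        for i, member in enumerate(model.members[1:], start=1):
            aux = model.aux[i - 1]
            nc = aux.n_coarse
            fl = 0
            F = in_features
            for C in (w.shape[1] for w in aux.W):  # auxiliary pooling GCN
                fl += flops_gcn_layer(n_prev, F, nnz_prev, C)
                F = C
            # S^T X, S^T Z S, prolongation of the coarse output
            fl += flops_matmul(nc, in_features, n_prev)
            fl += flops_matmul(nc, n_prev, n_prev) + flops_matmul(nc, nc, n_prev)
            fl += flops_matmul(n_fine, 1, nc)
            nnz_prev = nc * nc  # pooled structure matrix is dense
            fl += _member_flops(nc, nnz_prev, in_features, member, ledger, f"level{i}.")
            if ledger is not None:
                ledger.add(f"level{i}.pooling", fl)
            n_prev = nc
            per_level.append(fl)
    else:  # pragma: no cover
        raise TypeError(f"unknown model type {type(model)!r}")
    return per_level


# ---------------------------------------------------------------------------
# schedules
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScheduleSpec:
    kind: str = "joint"  # joint | mu_cycle | coarse_to_fine
    gamma: int | None = None
    patience: int = 10

    def __post_init__(self):
        if self.kind not in ("joint", "mu_cycle", "coarse_to_fine"):
            raise ValueError(f"unknown schedule kind {self.kind!r}")
        if self.kind == "mu_cycle":
            if self.gamma not in (0, 1, 2, 3):
                raise ValueError("gamma must be in {0,1,2,3} for mu_cycle")
        elif self.gamma is not None:
            raise ValueError("gamma is defined only for mu_cycle schedules")


def schedule_sequence(n_levels: int, spec: ScheduleSpec) -> list[frozenset[int]]:
    """Level-training events of one schedule unit (level 0 = finest).

    * ``joint``: a single event training every level (repeated each epoch).
    * ``mu_cycle``: one recursion cycle ``cycle(l) = [l] + gamma*cycle(l+1) +
      [l]`` started at the finest level (the coarsest level is a single
      visit); the training loop repeats the cycle until the epoch budget is
      spent.  With 3 levels and gamma=1 this is the V-cycle
      [fine, mid, coarse, mid, fine].
    * ``coarse_to_fine``: one event per phase (coarsest level, then
      coarsest+mid, ... then all); the training loop holds each phase until
      validation stalls for ``patience`` epochs.
    """
    if n_levels < 1:
        raise ValueError("need at least one level")
    all_levels = frozenset(range(n_levels))
    if spec.kind == "joint" or n_levels == 1:
        return [all_levels]
    if spec.kind == "coarse_to_fine":
        return [frozenset(range(lo, n_levels)) for lo in range(n_levels - 1, -1, -1)]

    def cycle(level: int) -> list[frozenset[int]]:
        if level == n_levels - 1:
            return [frozenset({level})]
        inner: list[frozenset[int]] = []
        for _ in range(spec.gamma):
            inner.extend(cycle(level + 1))
        return [frozenset({level})] + inner + [frozenset({level})]

    return cycle(0)


# ---------------------------------------------------------------------------
# optimizer and training loop
# ---------------------------------------------------------------------------


class Adam:
    def __init__(self, params: list[Var], config: TrainConfig):
        self.config = config
        self.state: dict[int, tuple[np.ndarray, np.ndarray, int]] = {
            id(p): (np.zeros_like(p.value), np.zeros_like(p.value), 0) for p in params
        }

    def step(self, params: list[Var]) -> None:
        c = self.config
        for p in params:
            if p.grad is None:
                continue
            m, v, t = self.state[id(p)]
            t += 1
            m = c.beta1 * m + (1 - c.beta1) * p.grad
            v = c.beta2 * v + (1 - c.beta2) * p.grad**2
            mhat = m / (1 - c.beta1**t)
            vhat = v / (1 - c.beta2**t)
            p.value -= c.learning_rate * mhat / (np.sqrt(vhat) + c.eps)
            self.state[id(p)] = (m, v, t)


def _event_flops(model, in_features: int, batch_samples: int,
                 levels: frozenset[int], per_level: list[int]) -> int:
    """Forward over all levels + backward over the trainable ones."""
    fwd = sum(per_level)
    if hasattr(model, "n_levels") and len(per_level) > 1:
        bwd = sum(per_level[l] for l in levels if l < len(per_level))
    else:  # single-scale models: backward covers everything
        bwd = fwd
    return (fwd + bwd) * batch_samples


def train(
    model,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    config: TrainConfig,
    schedule: ScheduleSpec | None = None,
) -> pd.DataFrame:
    """Train a model on standardized frames; returns the epoch history.

    One event = one epoch of ``batches_per_epoch`` batches.  The loss is
    always the fine-scale MSE of the full ensemble forward; an event updates
    only the member parameters of its levels (plus the corresponding P
    matrices when the model is adaptive).  History columns: ``epoch``,
    ``cum_flops``, ``train_mse``, ``val_nmse``, ``min_val_nmse``.
    """
    schedule = schedule or ScheduleSpec("joint")
    n_levels = getattr(model, "n_levels", 1)
    events = schedule_sequence(n_levels, schedule)
    in_features = X_train.shape[-1]
    per_level = model_flops(model, in_features)

    rng = np.random.default_rng(config.seed)
    all_params = model.parameters()
    opt = Adam(all_params, config)
    n_train = X_train.shape[0]
    order = rng.permutation(n_train)
    cursor = 0

    def next_batch():
        nonlocal order, cursor
        if cursor + config.batch_size > n_train:
            order = rng.permutation(n_train)
            cursor = 0
        idx = order[cursor : cursor + config.batch_size]
        cursor += config.batch_size
        return X_train[idx], y_train[idx]

    def trainable(levels: frozenset[int]) -> list[Var]:
        if len(levels) >= n_levels and hasattr(model, "parameters"):
            return all_params
        params: list[Var] = []
        for l in sorted(levels):
            params.extend(model.level_parameters(l))
        return params

    history = []
    best_val = np.inf
    epoch = 0
    event_iter = _event_stream(events, schedule, n_levels)
    while epoch < config.epochs:
        levels = next(event_iter)
        params = trainable(levels)
        batch_losses = []
        for _ in range(config.batches_per_epoch):
            Xb, yb = next_batch()
            for p in all_params:
                p.grad = None
            out = model.forward(Var(Xb, requires_grad=False))
            loss = ad.mean_square_error(out, yb)
            if not np.isfinite(loss.value):
                raise FloatingPointError(
                    f"divergent training loss at epoch {epoch}: {loss.value}"
                )
            ad.backward(loss)
            opt.step(params)
            batch_losses.append(float(loss.value))
        epoch += 1
        val_pred = model.predict(X_val)
        val = nmse(val_pred, y_val)
        improved = val < best_val - 1e-12
        best_val = min(best_val, val)
        flops = _event_flops(
            model, in_features, config.batch_size * config.batches_per_epoch,
            levels, per_level,
        )
        history.append(
            dict(
                epoch=epoch,
                levels="+".join(map(str, sorted(levels))),
                event_flops=flops,
                train_mse=float(np.mean(batch_losses)),
                val_nmse=val,
                min_val_nmse=best_val,
            )
        )
        if schedule.kind == "coarse_to_fine":
            event_iter.send_improved(improved)
    df = pd.DataFrame(history)
    df["cum_flops"] = df["event_flops"].cumsum()
    return df


class _event_stream:
    """Infinite stream of schedule events; phase advance driven by patience."""

    def __init__(self, events: list[frozenset[int]], spec: ScheduleSpec, n_levels: int):
        self.events = events
        self.spec = spec
        self.pos = 0
        self.stall = 0

    def __next__(self) -> frozenset[int]:
        if self.spec.kind == "coarse_to_fine":
            return self.events[min(self.pos, len(self.events) - 1)]
        ev = self.events[self.pos % len(self.events)]
        self.pos += 1
        return ev

    def send_improved(self, improved: bool) -> None:
        if self.spec.kind != "coarse_to_fine":
            return
        self.stall = 0 if improved else self.stall + 1
        if self.stall >= self.spec.patience and self.pos < len(self.events) - 1:
            self.pos += 1
            self.stall = 0


def flops_to_reach(history: pd.DataFrame, threshold: float) -> float:
    """Cumulative FLOPs at which min validation NMSE first reaches threshold."""
    hit = history[history["min_val_nmse"] <= threshold]
    return float(hit["cum_flops"].iloc[0]) if len(hit) else float("inf")
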