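"""Training protocol for the splice-site network.

Categorical cross-entropy, SGD with Nesterov momentum (0.9), initial
learning rate 0.01 halved every five epochs, batch size 64, 20 epochs;
the epoch with the best validation accuracy supplies the final weights, and
each configuration is trained for ``repeats`` independent runs whose results
are averaged. A reduced-scale per-stage grid search mirrors the
hyperparameter selection procedure.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

from . import nn
from .datasets import DatasetSplits, encode_splits
from .model import Network, NetworkSpec, StageConfig, build_network, cost_report

__all__ = [
    "TrainingConfig",
    "EpochRecord",
    "RunResult",
    "TrainingResult",
    "SearchBudget",
    "lr_schedule",
    "fit",
    "grid_search",
]

EncodedSplits = Mapping[str, tuple[np.ndarray, np.ndarray]]


class TrainingError(ValueError):
    pass


@dataclass(frozen=True)
class TrainingConfig:
    momentum: float = 0.9
    nesterov: bool = True
    initial_lr: float = 0.01
    halve_every: int = 5
    epochs: int = 20
    batch_size: int = 64
    repeats: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.initial_lr < 0:
            raise TrainingError("learning rate must be >= 0")
        if self.epochs < 1 or self.batch_size < 1 or self.repeats < 1:
            raise TrainingError("epochs, batch_size and repeats must be >= 1")


@dataclass(frozen=True)
class EpochRecord:
    epoch: int
    lr: float
    loss: float
    val_acc: float


@dataclass
class RunResult:
    history: list[EpochRecord]
    selected_epoch: int
    best_val_acc: float
    best_weights: list[dict[str, np.ndarray]]
    test_acc: float | None = None


@dataclass
class TrainingResult:
    """Per-repeat results; ``network`` carries the best weights of the
    first run (the reference model for downstream analysis)."""

    runs: list[RunResult]
    network: Network
    config: TrainingConfig

    @property
    def mean_val_acc(self) -> float:
        return float(np.mean([r.best_val_acc for r in self.runs]))

    @property
    def mean_test_acc(self) -> float | None:
        accs = [r.test_acc for r in self.runs]
        if any(a is None for a in accs):
            return None
        return float(np.mean(accs))


def lr_schedule(epoch: int, config: TrainingConfig) -> float:
    """Learning rate for a 1-based epoch: the initial rate halved at every
    ``halve_every``-epoch boundary (epochs 1-5 at 0.01, 6-10 at 0.005, ...)."""
    if not 1 <= epoch <= config.epochs:
        raise TrainingError(
            f"epoch {epoch} outside the training range 1..{config.epochs}"
        )
    return config.initial_lr * 0.5 ** ((epoch - 1) // config.halve_every)


class _SGD:
    """SGD with (Nesterov) momentum over all network parameters."""

    def __init__(self, network: Network, momentum: float, nesterov: bool) -> None:
        self.slots = [
            (layer, name, np.zeros_like(p))
            for layer in network.body.layers()
            for name, p in layer.params.items()
        ]
        self.momentum = momentum
        self.nesterov = nesterov

    def step(self, lr: float) -> None:
        mu = self.momentum
        for layer, name, v in self.slots:
            g = layer.grads[name]
            v *= mu
            v -= lr * g
            if self.nesterov:
                layer.params[name] += mu * v - lr * g
            else:
                layer.params[name] += v


def _accuracy(network: Network, X: np.ndarray, Y: np.ndarray,
              batch_size: int = 256) -> float:
    correct = 0
    for i in range(0, len(X), batch_size):
        p = network.predict_proba(X[i : i + batch_size])
        correct += int((p.argmax(axis=1) == Y[i : i + batch_size].argmax(axis=1)).sum())
    return correct / len(X)


def _as_encoded(splits: DatasetSplits | EncodedSplits) -> EncodedSplits:
    if isinstance(splits, DatasetSplits):
        return encode_splits(splits)
    return splits


def _train_one_run(spec: NetworkSpec, splits: EncodedSplits,
                   config: TrainingConfig, run_seed: int,
                   evaluate_test: bool) -> RunResult:
    Xtr, Ytr = splits["train"]
    Xva, Yva = splits["validation"]
    if len(Xtr) == 0 or len(Xva) == 0:
        raise TrainingError("train and validation splits must be non-empty")
    network = build_network(spec, seed=run_seed)
    opt = _SGD(network, config.momentum, config.nesterov)
    rng = np.random.default_rng(run_seed + 1)

    history: list[EpochRecord] = []
    best: tuple[float, int, list] | None = None  # (val_acc, epoch, weights)
    for epoch in range(1, config.epochs + 1):
        lr = lr_schedule(epoch, config)
        order = rng.permutation(len(Xtr))
        losses = []
        for start in range(0, len(order), config.batch_size):
            idx = order[start : start + config.batch_size]
            Xb, Yb = Xtr[idx], Ytr[idx]
            logits = network.logits(Xb, training=True)
            p = nn.softmax(logits)
            losses.append(float(-(Yb * np.log(p + 1e-12)).sum() / len(Xb)))
            network.zero_grads()
            network.backward((p - Yb) / len(Xb))
            opt.step(lr)
        val_acc = _accuracy(network, Xva, Yva)
        history.append(EpochRecord(epoch, lr, float(np.mean(losses)), val_acc))
        if best is None or val_acc > best[0]:
            best = (val_acc, epoch, network.get_weights())

    assert best is not None
    network.set_weights(best[2])
    test_acc = None
    if evaluate_test and "test" in splits and len(splits["test"][0]):
        test_acc = _accuracy(network, *splits["test"])
    return RunResult(
        history=history,
        selected_epoch=best[1],
        best_val_acc=best[0],
        best_weights=best[2],
        test_acc=test_acc,
    )


def fit(network_or_spec: Network | NetworkSpec,
        splits: DatasetSplits | EncodedSplits,
        config: TrainingConfig = TrainingConfig(),
        evaluate_test: bool = True) -> TrainingResult:
    """Train for ``config.repeats`` independent runs and return per-run and
    averaged results.

    Each run rebuilds the network from its spec with a distinct seed, trains
    for the configured epochs under the halving schedule, and restores the
    weights of the epoch with the highest validation accuracy. Runs are
    deterministic for a fixed seed.
    """
    spec = (
        network_or_spec.spec
        if isinstance(network_or_spec, Network)
        else network_or_spec
    )
    encoded = _as_encoded(splits)
    runs = [
        _train_one_run(spec, encoded, config, config.seed + r, evaluate_test)
        for r in range(config.repeats)
    ]
    reference = build_network(spec, seed=config.seed)
    reference.set_weights(runs[0].best_weights)
    return TrainingResult(runs=runs, network=reference, config=config)


# ---------------------------------------------------------------------------
# Per-stage grid search
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SearchBudget:
    """Training budget for one grid-search candidate (reduced scale)."""

    epochs: int = 3
    max_train_examples: int = 1024
    batch_size: int = 64
    repeats: int = 1
    seed: int = 0


STAGE_KEYS = ("stem", "stage2", "stage3", "stage4", "stage5")

Candidate = tuple[str, int, int, int]  # (stage_key, n, k, p)


def _with_stage(spec: NetworkSpec, key: str, n: int, k: int, p: int) -> NetworkSpec:
    if key == "stem":
        return replace(spec, stem=StageConfig(n=n, k=k, p=1))
    i = STAGE_KEYS.index(key) - 1
    stages = list(spec.stages)
    stages[i] = StageConfig(n=n, k=k, p=p)
    return replace(spec, stages=tuple(stages))


def grid_search(
    search_space: Mapping[str, Mapping[str, Sequence[int]]],
    splits: DatasetSplits | EncodedSplits | None,
    budget: SearchBudget = SearchBudget(),
    base_spec: NetworkSpec | None = None,
    scores: Mapping[Candidate, float] | None = None,
) -> tuple[NetworkSpec, list[dict]]:
    """Per-stage grid search: each stage's (N, K, P) grid is enumerated with
    the other stages held at the base spec — not the full Cartesian product
    across stages.

    ``search_space`` maps a stage key ('stem', 'stage2'..'stage5') to lists
    for 'n', 'k' and (except the stem) 'p'. Candidates are scored by
    validation accuracy after training under ``budget``; a precomputed
    ``scores`` table may replace training. Ties break toward fewer
    parameters, then first-seen order. Returns the assembled best spec and
    a scoreboard of every candidate evaluated.
    """
    if not search_space:
        raise TrainingError("empty search space")
    spec = base_spec if base_spec is not None else NetworkSpec.default()
    encoded = _as_encoded(splits) if splits is not None else None
    if encoded is None and scores is None:
        raise TrainingError("either data splits or a score table is required")

    scoreboard: list[dict] = []
    best_spec = spec
    for key in STAGE_KEYS:
        if key not in search_space:
            continue
        grid = search_space[key]
        ns = list(grid.get("n", [getattr_stage(best_spec, key).n]))
        ks = list(grid.get("k", [getattr_stage(best_spec, key).k]))
        ps = [1] if key == "stem" else list(grid.get("p", [getattr_stage(best_spec, key).p]))
        if not ns or not ks or not ps:
            raise TrainingError(f"empty grid for {key}")
        best_for_stage: tuple[float, int, int, NetworkSpec] | None = None
        for order_idx, (n, k, p) in enumerate(itertools.product(ns, ks, ps)):
            candidate = _with_stage(best_spec, key, n, k, p)
            if scores is not None:
                acc = scores[(key, n, k, p)]
            else:
                assert encoded is not None
                acc = _score_candidate(candidate, encoded, budget)
            n_params = cost_report(candidate).params
            scoreboard.append(
                {"stage": key, "n": n, "k": k, "p": p,
                 "val_acc": acc, "params": n_params}
            )
            rank = (-acc, n_params, order_idx)
            if best_for_stage is None or rank < best_for_stage[:3]:
                best_for_stage = (*rank, candidate)
        assert best_for_stage is not None
        best_spec = best_for_stage[3]
    return best_spec, scoreboard


def getattr_stage(spec: NetworkSpec, key: str) -> StageConfig:
    if key == "stem":
        return spec.stem
    return spec.stages[STAGE_KEYS.index(key) - 1]


def _score_candidate(spec: NetworkSpec, encoded: EncodedSplits,
                     budget: SearchBudget) -> float:
    Xtr, Ytr = encoded["train"]
    n = min(len(Xtr), budget.max_train_examples)
    sub = dict(encoded)
    sub["train"] = (Xtr[:n], Ytr[:n])
    cfg = TrainingConfig(
        epochs=budget.epochs,
        batch_size=budget.batch_size,
        repeats=budget.repeats,
        seed=budget.seed,
    )
    result = fit(spec, sub, cfg, evaluate_test=False)
    return result.mean_val_acc
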