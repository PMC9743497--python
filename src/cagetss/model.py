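"""The four-branch convolutional peak classifier.

One convolutional branch per feature family (one-hot sequence, GSP signals,
structural profiles, conservation), each with two valid convolutions
(leaky-ReLU activation followed by batch normalization after every
convolutional and dense layer), flattened and concatenated into a
three-layer dense head with dropout and a single sigmoid output unit.
Training minimizes binary cross-entropy with Adam and early-stops on
validation loss, restoring the best-validation weights.

Defaults: sequence/GSP/structural branches 20/10 filters with 16/12
kernels; conservation branch 32/16 filters with 16/8 kernels; dense head
120/60/25; dropout 0.2; learning rate 0.001; batch 256; at most 60 epochs
with patience 10.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from cagetss import nn
from cagetss.features import (
    FeatureBundle,
    StandardizationStats,
    fit_standardizer,
)

BRANCH_CHANNELS = {"onehot": 4, "gsp": 8, "structural": 2, "conservation": 1}
ALL_BRANCHES = ("onehot", "gsp", "structural", "conservation")


@dataclass(frozen=True)
class BranchSpec:
    filters1: int
    filters2: int
    kernel1: int
    kernel2: int


DEFAULT_BRANCH_SPECS: Dict[str, BranchSpec] = {
    "onehot": BranchSpec(20, 10, 16, 12),
    "gsp": BranchSpec(20, 10, 16, 12),
    "structural": BranchSpec(20, 10, 16, 12),
    "conservation": BranchSpec(32, 16, 16, 8),
}

#: Published hyperparameter search space (exposed for grid_search; the
#: defaults above are the selected combination).
GRID_SEARCH_SPACE = {
    "filters": (20, 30, 40),
    "kernels": ((20, 15), (16, 12), (12, 8)),
    "dense": ((140, 80, 40), (120, 60, 25), (100, 60, 20)),
    "learning_rate": (0.01, 0.001, 0.0005, 0.0001),
    "batch_size": (64, 128, 256, 512),
    "dropout": (0.2, 0.25, 0.3, 0.35),
}


@dataclass(frozen=True)
class ModelConfig:
    branch_specs: Dict[str, BranchSpec] = field(
        default_factory=lambda: dict(DEFAULT_BRANCH_SPECS))
    enabled_branches: Tuple[str, ...] = ALL_BRANCHES
    dense: Tuple[int, int, int] = (120, 60, 25)
    dropout: float = 0.2
    learning_rate: float = 0.001
    batch_size: int = 256
    epochs: int = 60
    patience: int = 10
    leaky_alpha: float = 0.01
    seed: int = 0
    window: int = 600

    def to_dict(self) -> dict:
        d = asdict(self)
        d["branch_specs"] = {k: asdict(v) for k, v in self.branch_specs.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d["branch_specs"] = {
            k: BranchSpec(**v) for k, v in d["branch_specs"].items()
        }
        d["enabled_branches"] = tuple(d["enabled_branches"])
        d["dense"] = tuple(d["dense"])
        return cls(**d)


def _branch(spec: BranchSpec, in_ch: int, alpha: float,
            rng: np.random.Generator) -> nn.Sequential:
    return nn.Sequential([
        nn.Conv1D(in_ch, spec.filters1, spec.kernel1, rng),
        nn.LeakyReLU(alpha),
        nn.BatchNorm(spec.filters1),
        nn.Conv1D(spec.filters1, spec.filters2, spec.kernel2, rng),
        nn.LeakyReLU(alpha),
        nn.BatchNorm(spec.filters2),
        nn.Flatten(),
    ])


def _branch_out_width(spec: BranchSpec, window: int) -> int:
    l1 = window - spec.kernel1 + 1
    l2 = l1 - spec.kernel2 + 1
    return l2 * spec.filters2


def build_model(config: ModelConfig,
                rng: Optional[np.random.Generator] = None) -> nn.MultiBranchNet:
    """Construct the (untrained) multi-branch network from a config."""
    if not config.enabled_branches:
        raise ValueError("at least one branch must be enabled")
    for name in config.enabled_branches:
        if name not in BRANCH_CHANNELS:
            raise ValueError(f"unknown branch {name!r}")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    branches = {
        name: _branch(config.branch_specs[name], BRANCH_CHANNELS[name],
                      config.leaky_alpha, rng)
        for name in config.enabled_branches
    }
    concat = sum(_branch_out_width(config.branch_specs[n], config.window)
                 for n in config.enabled_branches)
    d1, d2, d3 = config.dense
    head = nn.Sequential([
        nn.Dense(concat, d1, rng),
        nn.LeakyReLU(config.leaky_alpha),
        nn.BatchNorm(d1),
        nn.Dropout(config.dropout, rng),
        nn.Dense(d1, d2, rng),
        nn.LeakyReLU(config.leaky_alpha),
        nn.BatchNorm(d2),
        nn.Dropout(config.dropout, rng),
        nn.Dense(d2, d3, rng),
        nn.LeakyReLU(config.leaky_alpha),
        nn.BatchNorm(d3),
        nn.Dropout(config.dropout, rng),
        nn.Dense(d3, 1, rng),
    ])
    return nn.MultiBranchNet(branches, head)


def stack_bundles(bundles: Sequence[FeatureBundle],
                  branches: Sequence[str] = ALL_BRANCHES) -> Dict[str, np.ndarray]:
    """Stack per-peak feature blocks into per-branch (N, 600, C) arrays."""
    return {
        name: np.stack([getattr(b, name) for b in bundles]).astype(nn.DTYPE)
        for name in branches
    }


def _standardize_stacked(inputs: Dict[str, np.ndarray],
                         stats: StandardizationStats) -> Dict[str, np.ndarray]:
    out = dict(inputs)
    if "gsp" in out:
        out["gsp"] = ((out["gsp"] - stats.gsp_mean) / stats.gsp_sd).astype(nn.DTYPE)
    if "structural" in out:
        out["structural"] = ((out["structural"] - stats.structural_mean)
                             / stats.structural_sd).astype(nn.DTYPE)
    return out


@dataclass
class TrainedModel:
    """Network weights plus everything needed to score new peaks.

    The standardization statistics are persisted with the weights; scoring
    always applies them first, and loading refuses shape mismatches.
    """

    net: nn.MultiBranchNet
    stats: StandardizationStats
    config: ModelConfig
    history: Dict[str, List[float]]

    def save(self, directory: str) -> None:
        os.makedirs(directory, exist_ok=True)
        arrays = {f"p{i}": a for i, a in enumerate(self.net.params())}
        arrays.update({f"s{i}": a for i, a in enumerate(self.net.state())})
        np.savez(os.path.join(directory, "weights.npz"), **arrays)
        with open(os.path.join(directory, "model.json"), "w") as fh:
            json.dump({
                "config": self.config.to_dict(),
                "standardizer": self.stats.to_dict(),
                "history": self.history,
            }, fh, indent=1)

    @classmethod
    def load(cls, directory: str) -> "TrainedModel":
        with open(os.path.join(directory, "model.json")) as fh:
            meta = json.load(fh)
        config = ModelConfig.from_dict(meta["config"])
        stats = StandardizationStats.from_dict(meta["standardizer"])
        net = build_model(config)
        data = np.load(os.path.join(directory, "weights.npz"))
        params, state = net.params(), net.state()
        for i, p in enumerate(params):
            saved = data[f"p{i}"]
            if saved.shape != p.shape:
                raise ValueError(
                    f"weight {i} shape {saved.shape} incompatible with "
                    f"config shape {p.shape}"
                )
            p[...] = saved
        for i, s in enumerate(state):
            s[...] = data[f"s{i}"]
        return cls(net, stats, config, meta["history"])


def _epoch_pass(net, inputs, y, config, rng, optimizer) -> float:
    n = y.shape[0]
    order = rng.permutation(n)
    total = 0.0
    for start in range(0, n, config.batch_size):
        idx = order[start:start + config.batch_size]
        batch = {k: v[idx] for k, v in inputs.items()}
        logits = net.forward(batch, training=True)
        loss = nn.bce_with_logits(logits, y[idx])
        if not np.isfinite(loss):
            raise RuntimeError(
                f"non-finite training loss {loss} at examples "
                f"{start}..{start + len(idx)}; check inputs and learning rate"
            )
        total += loss * len(idx)
        p = nn.sigmoid(logits)
        dlogit = ((p - y[idx]) / len(idx)).astype(nn.DTYPE)
        net.backward(dlogit)
        optimizer.step(net.grads())
    return total / n


def _eval_loss(net, inputs, y, batch_size: int) -> float:
    n = y.shape[0]
    total = 0.0
    for start in range(0, n, batch_size):
        sl = slice(start, start + batch_size)
        batch = {k: v[sl] for k, v in inputs.items()}
        logits = net.forward(batch, training=False)
        total += nn.bce_with_logits(logits, y[sl]) * (min(n, start + batch_size) - start)
    return total / n


def train(train_bundles: Sequence[FeatureBundle],
          train_labels: Sequence[int],
          val_bundles: Sequence[FeatureBundle],
          val_labels: Sequence[int],
          config: ModelConfig = ModelConfig()) -> TrainedModel:
    """Fit the classifier: standardize (statistics from the training set
    only), minimize binary cross-entropy with Adam, early-stop on
    validation loss with the configured patience, and restore the weights
    of the best-validation epoch."""
    if not len(train_bundles) or not len(val_bundles):
        raise ValueError("training and validation sets must be non-empty")
    rng = np.random.default_rng(config.seed)
    net = build_model(config, rng)
    stats = fit_standardizer(train_bundles)
    xtr = _standardize_stacked(
        stack_bundles(train_bundles, config.enabled_branches), stats)
    xval = _standardize_stacked(
        stack_bundles(val_bundles, config.enabled_branches), stats)
    ytr = np.asarray(train_labels, dtype=np.float64)
    yval = np.asarray(val_labels, dtype=np.float64)

    optimizer = nn.Adam(net.params(), lr=config.learning_rate)
    history: Dict[str, List[float]] = {"train_loss": [], "val_loss": []}
    best_val = np.inf
    best_params = nn.snapshot(net.params())
    best_state = nn.snapshot(net.state())
    since_best = 0
    for _ in range(config.epochs):
        tr_loss = _epoch_pass(net, xtr, ytr, config, rng, optimizer)
        val_loss = _eval_loss(net, xval, yval, config.batch_size)
        history["train_loss"].append(tr_loss)
        history["val_loss"].append(val_loss)
        if val_loss < best_val:
            best_val = val_loss
            best_params = nn.snapshot(net.params())
            best_state = nn.snapshot(net.state())
            since_best = 0
        else:
            since_best += 1
            if since_best > config.patience:
                break
    nn.restore(net.params(), best_params)
    nn.restore(net.state(), best_state)
    return TrainedModel(net, stats, config, history)


def score(model: TrainedModel, bundles: Sequence[FeatureBundle],
          batch_size: int = 256) -> np.ndarray:
    """Probability that each peak is a true transcription-initiation event.

    Applies the persisted standardizer, runs the network in inference mode
    (batch norm on stored statistics, dropout off); the result is
    independent of batch order and size.
    """
    if not len(bundles):
        return np.zeros(0)
    inputs = _standardize_stacked(
        stack_bundles(bundles, model.config.enabled_branches), model.stats)
    n = next(iter(inputs.values())).shape[0]
    probs = np.empty(n, dtype=np.float64)
    for start in range(0, n, batch_size):
        sl = slice(start, start + batch_size)
        batch = {k: v[sl] for k, v in inputs.items()}
        probs[sl] = nn.sigmoid(model.net.forward(batch, training=False))
    return probs


def classify(scores: np.ndarray, cutoff: float = 0.9) -> np.ndarray:
    """Binary call per peak: positive iff score >= cutoff (default 0.9)."""
    return (np.asarray(scores) >= cutoff).astype(int)
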