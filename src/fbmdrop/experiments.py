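"""Benchmark experiments: overfitting with and without fiber dropout.

Two experiments probe how spatially correlated, fiber-driven dropout
compares with the standard Bernoulli dropout and with no dropout at all:

* **Regression** — a 1-100-100-1 ReLU network trained on 50 noisy points
  of a line (Adam, lr 0.01, 50 epochs of 50 single-sample mini-batches).
  Without dropout the network memorizes the noise; the generalization gap
  (testing loss minus training loss) grows with training.
* **Image classification** — a 784-1024-1024-10 ReLU network on a reduced
  digit set of 1,000 training and 1,000 testing images (Adam, lr 0.0001,
  100 epochs of 64-sample mini-batches).

Dropout acts on the two hidden layers only (their widths are perfect
squares, so each embeds as an N x N neuron grid); inputs and outputs are
never masked.  Each hidden layer carries its own independent fiber set.
Fibers advance one window shift per mini-batch iteration and branch at
each epoch end.  Masks are recomputed every iteration in all modes.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .datasets import ImageData, RegressionData
from .dropout import (
    DROPOUT_MODES,
    apply_mask,
    calibrate_fiber_count,
    mask_from_points,
    standard_dropout_mask,
)
from .fibers import FiberParams, init_fibers
from .geometry import build_grid
from .nn import MLP


@dataclass(frozen=True)
class ExperimentConfig:
    """Full configuration of one training run.

    ``layer_sizes`` is ``(n_in, h, h, n_out)``; the hidden widths must be
    perfect squares so the layers embed as neuron grids.  ``n_fibers=None``
    with mode ``"fbm"`` triggers calibration to ``target_rate``.
    """

    task: str  # "regression" | "classification"
    layer_sizes: tuple
    mode: str = "none"
    target_rate: float = 0.2
    n_fibers: int | None = None
    window_len: int = 50
    shift: int = 50
    hurst: float = 0.9
    sigma: float = 1.0
    dt: float = 1.0 / 500.0
    lr: float = 0.01
    epochs: int = 50
    batch_size: int = 1
    inverted_scaling: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.task not in ("regression", "classification"):
            raise ValueError(f"unknown task {self.task!r}")
        if self.mode not in DROPOUT_MODES:
            raise ValueError(f"mode must be one of {DROPOUT_MODES}, got {self.mode!r}")
        if len(self.layer_sizes) != 4:
            raise ValueError("layer_sizes must be (n_in, hidden, hidden, n_out)")
        if self.epochs < 1:
            raise ValueError(f"epochs must be positive, got {self.epochs}")
        if self.batch_size < 1:
            raise ValueError(f"batch_size must be positive, got {self.batch_size}")
        if self.mode != "none":
            for width in self.layer_sizes[1:3]:
                side = math.isqrt(int(width))
                if side * side != width:
                    raise ValueError(
                        f"hidden width {width} is not a perfect square; "
                        "cannot embed the layer as an N x N neuron grid"
                    )

    @property
    def grid_sides(self) -> tuple[int, int]:
        return (
            math.isqrt(int(self.layer_sizes[1])),
            math.isqrt(int(self.layer_sizes[2])),
        )

    def iters_per_epoch(self, n_train: int) -> int:
        if n_train < 1:
            raise ValueError("training set is empty")
        return math.ceil(n_train / self.batch_size)


# Paper-scale presets for the two benchmarks.
def regression_config(mode: str = "none", seed: int = 0, **overrides) -> ExperimentConfig:
    base = dict(
        task="regression",
        layer_sizes=(1, 100, 100, 1),
        mode=mode,
        n_fibers=12 if mode == "fbm" else None,
        lr=0.01,
        epochs=50,
        batch_size=1,
        seed=seed,
    )
    base.update(overrides)
    return ExperimentConfig(**base)


def mnist_config(mode: str = "none", seed: int = 0, **overrides) -> ExperimentConfig:
    base = dict(
        task="classification",
        layer_sizes=(784, 1024, 1024, 10),
        mode=mode,
        n_fibers=60 if mode == "fbm" else None,
        lr=0.0001,
        epochs=100,
        batch_size=64,
        seed=seed,
    )
    base.update(overrides)
    return ExperimentConfig(**base)


@dataclass
class RunRecord:
    """Per-epoch trajectories of one training run."""

    condition: str
    train_loss: np.ndarray
    test_loss: np.ndarray
    test_accuracy: np.ndarray | None
    config: dict
    mean_drop_rate: float = 0.0
    n_fibers_used: int | None = None

    @property
    def gap(self) -> np.ndarray:
        """Generalization gap: testing loss minus training loss, per epoch."""
        return self.test_loss - self.train_loss

    @property
    def final_gap(self) -> float:
        return float(self.gap[-1])

    def to_dataframe(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            {
                "epoch": np.arange(1, self.train_loss.size + 1),
                "condition": self.condition,
                "train_loss": self.train_loss,
                "test_loss": self.test_loss,
                "gap": self.gap,
            }
        )
        if self.test_accuracy is not None:
            frame["accuracy"] = self.test_accuracy
        return frame

    def summary(self) -> dict:
        out = {
            "condition": self.condition,
            "final_train_loss": float(self.train_loss[-1]),
            "final_test_loss": float(self.test_loss[-1]),
            "final_gap": self.final_gap,
            "mean_drop_rate": self.mean_drop_rate,
            "n_fibers_used": self.n_fibers_used,
            "config": self.config,
        }
        if self.test_accuracy is not None:
            out["final_accuracy"] = float(self.test_accuracy[-1])
        return out

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=2)


def _training_arrays(config: ExperimentConfig, train_data, test_data):
    if config.task == "regression":
        if not isinstance(train_data, RegressionData):
            raise TypeError("regression task requires RegressionData")
        return train_data.x, train_data.y, test_data.x, test_data.y
    if not isinstance(train_data, ImageData):
        raise TypeError("classification task requires ImageData")
    if train_data.flat.shape[1] != config.layer_sizes[0]:
        raise ValueError(
            f"dataset width {train_data.flat.shape[1]} does not match "
            f"network input width {config.layer_sizes[0]}"
        )
    return train_data.flat, train_data.labels, test_data.flat, test_data.labels


def run_experiment(
    config: ExperimentConfig, train_data, test_data
) -> RunRecord:
    """Train one network under the configured dropout condition.

    Fiber sets advance one shift per mini-batch and branch at each epoch
    end; masks are recomputed every iteration.  Per-epoch losses are
    evaluated in eval mode (no dropout) on the full training and testing
    sets.  Fully reproducible: all randomness (weights, shuffling, fibers,
    Bernoulli masks) derives from ``config.seed``.
    """
    x_train, y_train, x_test, y_test = _training_arrays(config, train_data, test_data)
    n_train = x_train.shape[0]
    iters = config.iters_per_epoch(n_train)

    ss = np.random.SeedSequence(config.seed)
    s_weights, s_shuffle, s_fib1, s_fib2, s_bern, s_cal = ss.spawn(6)
    shuffle_rng = np.random.default_rng(s_shuffle)
    bern_rng = np.random.default_rng(s_bern)

    net = MLP(
        config.layer_sizes,
        task=config.task,
        lr=config.lr,
        seed=s_weights,
    )

    grids = [build_grid(n) for n in config.grid_sides]
    fiber_sets = None
    n_fibers = config.n_fibers
    if config.mode == "fbm":
        fparams = []
        for grid in grids:
            base = FiberParams(
                n_fibers=n_fibers or 1,
                iters_per_epoch=iters,
                window_len=config.window_len,
                shift=config.shift,
                hurst=config.hurst,
                sigma=config.sigma,
                dt=config.dt,
            )
            if n_fibers is None:
                n_cal = calibrate_fiber_count(
                    grid, base, config.target_rate, seed=s_cal
                )
            else:
                n_cal = n_fibers
            fparams.append(
                FiberParams(
                    n_fibers=n_cal,
                    iters_per_epoch=iters,
                    window_len=config.window_len,
                    shift=config.shift,
                    hurst=config.hurst,
                    sigma=config.sigma,
                    dt=config.dt,
                )
            )
        fiber_sets = [
            init_fibers(fp, seed) for fp, seed in zip(fparams, (s_fib1, s_fib2))
        ]
        n_fibers = fparams[0].n_fibers

    train_loss = np.empty(config.epochs)
    test_loss = np.empty(config.epochs)
    test_acc = np.empty(config.epochs) if config.task == "classification" else None
    rate_sum, rate_n = 0.0, 0

    for epoch in range(config.epochs):
        order = shuffle_rng.permutation(n_train)
        for it in range(iters):
            batch = order[it * config.batch_size : (it + 1) * config.batch_size]
            masks = None
            if config.mode != "none":
                masks = []
                for layer, grid in enumerate(grids):
                    if config.mode == "fbm":
                        _, pts = fiber_sets[layer].active_points(it)
                        m = mask_from_points(grid, pts, iteration=it)
                    else:
                        m = standard_dropout_mask(
                            grid.neuron_count, config.target_rate, bern_rng, it
                        )
                    rate_sum += m.realized_rate
                    rate_n += 1
                    keep = apply_mask(
                        np.ones(grid.neuron_count),
                        m,
                        training=True,
                        inverted=config.inverted_scaling,
                    )
                    masks.append(keep)
            net.train_step(x_train[batch], y_train[batch], masks)
        if fiber_sets is not None:
            for fs in fiber_sets:
                fs.branch_epoch()
        train_loss[epoch] = _eval_loss(net, x_train, y_train)
        if config.task == "classification":
            test_loss[epoch], test_acc[epoch] = net.evaluate(x_test, y_test)
        else:
            test_loss[epoch] = net.evaluate(x_test, y_test)

    cfg = asdict(config)
    cfg["layer_sizes"] = list(config.layer_sizes)
    return RunRecord(
        condition=config.mode,
        train_loss=train_loss,
        test_loss=test_loss,
        test_accuracy=test_acc,
        config=cfg,
        mean_drop_rate=rate_sum / rate_n if rate_n else 0.0,
        n_fibers_used=n_fibers,
    )


def _eval_loss(net: MLP, x, y) -> float:
    out = net.evaluate(x, y)
    return out[0] if isinstance(out, tuple) else out


def compare_conditions(
    base_config: ExperimentConfig,
    train_data,
    test_data,
    n_seeds: int = 10,
    modes=("none", "standard", "fbm"),
) -> "ComparisonResult":
    """Run all dropout conditions over several seeds on shared data.

    Every run differs only in the dropout mode and the seed; architecture,
    optimizer, data and drop-rate target are identical, and both dropout
    conditions target the same average rate.
    """
    from dataclasses import replace

    records: dict[str, list[RunRecord]] = {m: [] for m in modes}
    for mode in modes:
        for k in range(n_seeds):
            cfg = replace(base_config, mode=mode, seed=base_config.seed + k)
            if mode != "fbm":
                cfg = replace(cfg, n_fibers=None)
            records[mode].append(run_experiment(cfg, train_data, test_data))
    return ComparisonResult(records=records)


@dataclass
class ComparisonResult:
    """Per-condition run collections plus summary statistics."""

    records: dict

    def final_gaps(self, mode: str) -> np.ndarray:
        return np.array([r.final_gap for r in self.records[mode]])

    def summary(self) -> dict:
        out = {}
        for mode, runs in self.records.items():
            gaps = self.final_gaps(mode)
            out[mode] = {
                "median_final_gap": float(np.median(gaps)),
                "mean_final_gap": float(np.mean(gaps)),
                "sd_final_gap": float(np.std(gaps, ddof=1)) if len(gaps) > 1 else 0.0,
                "final_gaps": gaps.tolist(),
                "n_runs": len(runs),
            }
        return out

    def to_dataframe(self) -> pd.DataFrame:
        frames = []
        for mode, runs in self.records.items():
            for k, rec in enumerate(runs):
                frame = rec.to_dataframe()
                frame["seed_index"] = k
                frames.append(frame)
        return pd.concat(frames, ignore_index=True)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=2)
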