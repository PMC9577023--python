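"""Dropout masks: fiber-driven (spatially correlated) and Bernoulli.

A neuron is dropped in a training iteration when at least one active fiber
point lies inside its square cell; its output is then set to zero and it
contributes nothing to the forward pass or the gradients of that iteration.
Because a single fiber window is a short, contiguous piece of a trajectory,
neurons in close proximity tend to be dropped together — unlike the
standard baseline where every neuron is dropped independently with a fixed
probability ``p``.

The number of fibers ``n`` is the knob that sets the *average* drop rate
(more fibers, more neurons silenced); :func:`calibrate_fiber_count` finds
the ``n`` whose Monte-Carlo mean realized rate is closest to a target.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fbm import ParameterError
from .fibers import FiberParams, init_fibers
from .geometry import NeuronGrid, neuron_indices

DROPOUT_MODES = ("none", "standard", "fbm")


@dataclass(frozen=True)
class DropoutMask:
    """Boolean drop mask over one layer for one training iteration."""

    iteration: int
    dropped: np.ndarray  # bool, length neuron_count

    @property
    def realized_rate(self) -> float:
        """Fraction of the layer's neurons dropped this iteration."""
        return float(np.mean(self.dropped))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "iteration": self.iteration,
                "neuron_index": np.arange(self.dropped.size),
                "dropped": self.dropped,
            }
        )


def mask_from_points(
    grid: NeuronGrid, points: np.ndarray, iteration: int = 0
) -> DropoutMask:
    """Mask the union of neurons hit by any of the given (wrapped) points.

    Several fibers may hit the same neuron; the union semantics make that a
    no-op beyond the first hit.
    """
    dropped = np.zeros(grid.neuron_count, dtype=bool)
    points = np.asarray(points, dtype=float)
    if points.size:
        idx = neuron_indices(grid, points)
        dropped[idx[idx >= 0]] = True
    return DropoutMask(iteration=iteration, dropped=dropped)


def standard_dropout_mask(
    neuron_count: int,
    rate: float,
    rng: np.random.Generator | None = None,
    iteration: int = 0,
) -> DropoutMask:
    """Independent Bernoulli(rate) drop decisions per neuron."""
    if not (0.0 <= rate <= 1.0):
        raise ParameterError(f"rate must lie in [0, 1], got {rate}")
    if rng is None:
        rng = np.random.default_rng()
    dropped = rng.random(neuron_count) < rate
    return DropoutMask(iteration=iteration, dropped=dropped)


def apply_mask(
    activations: np.ndarray,
    mask: DropoutMask,
    training: bool = True,
    inverted: bool = False,
) -> np.ndarray:
    """Zero the masked units of an activation vector (or batch).

    In training mode masked entries become exactly 0; multiplying by the
    binary mask also removes them from backpropagation.  In evaluation mode
    activations pass through unchanged.  ``inverted=True`` additionally
    rescales surviving units by ``1/(1 - p)`` with ``p`` the realized rate;
    the experiment harness enables this symmetrically in all dropout modes.
    """
    activations = np.asarray(activations, dtype=float)
    if activations.shape[-1] != mask.dropped.size:
        raise ValueError(
            f"activation width {activations.shape[-1]} does not match mask "
            f"length {mask.dropped.size}"
        )
    if not training:
        return activations
    keep = (~mask.dropped).astype(float)
    if inverted:
        p = mask.realized_rate
        if p < 1.0:
            keep = keep / (1.0 - p)
    return activations * keep


def simulate_rates(
    grid: NeuronGrid,
    fiber_params: FiberParams,
    n_epochs: int,
    seed,
) -> np.ndarray:
    """Realized drop rates over a full schedule of epochs with branching.

    Returns one rate per iteration (``n_epochs * iters_per_epoch`` values);
    this is the quantity the paper-style configurations tune to ~0.2.
    """
    fibers = init_fibers(fiber_params, seed)
    rates = np.empty(n_epochs * fiber_params.iters_per_epoch)
    k = 0
    for _ in range(n_epochs):
        for it in range(fiber_params.iters_per_epoch):
            _, pts = fibers.active_points(it)
            rates[k] = mask_from_points(grid, pts, iteration=it).realized_rate
            k += 1
        fibers.branch_epoch()
    return rates


def _prefix_union_rates(
    grid: NeuronGrid,
    fiber_params: FiberParams,
    n_candidates: int,
    n_iterations: int,
    seed,
) -> np.ndarray:
    """Mean drop rate for fiber counts 1..n_candidates, from one simulation.

    Simulates ``n_candidates`` independent fibers over ``n_iterations``
    iterations (with epoch branching) and accumulates, per iteration, the
    union of hit neurons over the first ``n`` fibers.  Fibers are
    exchangeable, so the prefix unions estimate the mean realized rate of a
    population of ``n`` fibers; the estimate is non-decreasing in ``n`` by
    construction.
    """
    sim = FiberParams(
        n_fibers=n_candidates,
        iters_per_epoch=fiber_params.iters_per_epoch,
        window_len=fiber_params.window_len,
        shift=fiber_params.shift,
        hurst=fiber_params.hurst,
        sigma=fiber_params.sigma,
        dt=fiber_params.dt,
    )
    fibers = init_fibers(sim, seed)
    win = fiber_params.window_len + 1
    totals = np.zeros(n_candidates)
    done = 0
    while done < n_iterations:
        for it in range(sim.iters_per_epoch):
            if done >= n_iterations:
                break
            _, pts = fibers.active_points(it)
            idx = neuron_indices(grid, pts).reshape(n_candidates, win)
            hit = np.zeros((n_candidates, grid.neuron_count), dtype=bool)
            rows = np.repeat(np.arange(n_candidates), win)
            valid = idx.ravel() >= 0
            hit[rows[valid], idx.ravel()[valid]] = True
            union = np.logical_or.accumulate(hit, axis=0)
            totals += union.sum(axis=1)
            done += 1
        fibers.branch_epoch()
    return totals / (n_iterations * grid.neuron_count)


def calibrate_fiber_count(
    grid: NeuronGrid,
    fiber_params: FiberParams,
    target_rate: float,
    seed,
    n_iterations: int = 500,
    n_max: int = 4096,
) -> int:
    """Find the fiber count whose mean realized drop rate best matches target.

    Monte-Carlo search over ``n``; exploits that the mean rate is
    non-decreasing in the number of fibers.  Raises if the target exceeds
    the rate achievable with ``n_max`` fibers.
    """
    if not (0.0 < target_rate < 1.0):
        raise ParameterError(
            f"target_rate must lie strictly in (0, 1), got {target_rate}"
            " (use dropout mode 'none' for a zero rate)"
        )
    n_cand = max(4 * fiber_params.n_fibers, 16)
    while True:
        rates = _prefix_union_rates(grid, fiber_params, n_cand, n_iterations, seed)
        if rates[-1] >= target_rate or n_cand >= n_max:
            break
        n_cand = min(2 * n_cand, n_max)
    if rates[-1] < target_rate:
        raise ParameterError(
            f"target_rate {target_rate} is unattainable: achievable mean "
            f"rates span (0, {rates[-1]:.3f}] with up to {n_max} fibers"
        )
    return int(np.argmin(np.abs(rates - target_rate))) + 1
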