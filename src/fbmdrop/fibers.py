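"""Moving stochastic fibers: sliding windows over FBM paths with branching.

Each fiber is a sliding subarray of a long planar FBM path.  At training
iteration ``i`` the fiber occupies the ``L + 1`` path points with indices
``i*s .. i*s + L`` (the closed time interval ``[(i s) dt, (i s + L) dt]``),
where ``L`` is the fiber length in points and ``s`` the per-iteration shift.
With ``s = L`` the fiber advances fast, each window starting where the last
one ended; with ``s < L`` it crawls, retaining ``L - s + 1`` of its points.

At the end of every epoch each fiber *branches*: a fresh FBM path is grown
from a uniformly chosen point of the fiber's final window and the old path
degenerates (is discarded).  This keeps backing paths short — long-memory
FBM paths are expensive to extend — while letting fibers wander over the
whole layer across epochs.  Fibers do not interact; coordinates are wrapped
periodically into the unit square only when queried, so the wrap never
distorts the increment process.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fbm import FBMParams, ParameterError, sample_fgn
from .geometry import wrap_periodic


@dataclass(frozen=True)
class FiberParams:
    """Configuration of a fiber population.

    ``shift <= window_len`` is required: a shift larger than the window
    would skip path segments, which the sliding-window model never does.
    The backing-path length is derived from the epoch schedule so the last
    window of an epoch exactly reaches the end of the path.
    """

    n_fibers: int
    iters_per_epoch: int
    window_len: int = 50
    shift: int = 50
    hurst: float = 0.9
    sigma: float = 1.0
    dt: float = 1.0 / 500.0

    def __post_init__(self) -> None:
        if self.n_fibers < 1:
            raise ParameterError(
                f"n_fibers must be a positive integer, got {self.n_fibers}"
                " (disable dropout entirely rather than using zero fibers)"
            )
        if self.iters_per_epoch < 1:
            raise ParameterError(
                f"iters_per_epoch must be positive, got {self.iters_per_epoch}"
            )
        if self.window_len < 1:
            raise ParameterError(f"window_len must be positive, got {self.window_len}")
        if self.shift < 1:
            raise ParameterError(f"shift must be positive, got {self.shift}")
        if self.shift > self.window_len:
            raise ParameterError(
                f"shift ({self.shift}) must not exceed window_len "
                f"({self.window_len}); larger shifts would leave unused gaps"
            )
        # Validate the FBM parameters eagerly.
        FBMParams(hurst=self.hurst, sigma=self.sigma, t_max=self.dt, dt=self.dt)

    @property
    def points_per_epoch(self) -> int:
        """Backing-path points needed for one epoch (incl. the start point)."""
        return (self.iters_per_epoch - 1) * self.shift + self.window_len + 1

    @property
    def fbm_params(self) -> FBMParams:
        """FBM parameters of one epoch's backing path."""
        return FBMParams(
            hurst=self.hurst,
            sigma=self.sigma,
            t_max=(self.points_per_epoch - 1) * self.dt,
            dt=self.dt,
        )


class FiberSet:
    """A population of independent moving fibers over one layer.

    Use :func:`init_fibers` to construct.  Per-fiber random substreams are
    spawned from the master seed, so results are reproducible and each
    fiber's trajectory is unaffected by the presence of the others.
    """

    def __init__(self, params: FiberParams, seed) -> None:
        self.params = params
        self.epoch_index = 0
        ss = (
            seed
            if isinstance(seed, np.random.SeedSequence)
            else np.random.SeedSequence(seed)
        )
        self._rngs = [np.random.default_rng(s) for s in ss.spawn(params.n_fibers)]
        self._paths: list[np.ndarray] = []
        for rng in self._rngs:
            origin = rng.uniform(0.0, 1.0, size=2)
            self._paths.append(self._grow_path(origin, rng))

    def _grow_path(self, origin: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Fresh unwrapped 2-D path of one epoch's length, from ``origin``."""
        fgn = sample_fgn(self.params.fbm_params, 2, rng)  # x and y increments
        path = np.empty((self.params.points_per_epoch, 2))
        path[0] = origin
        np.cumsum(fgn.T, axis=0, out=path[1:])
        path[1:] += origin
        return path

    def window_indices(self, iteration: int) -> np.ndarray:
        """Path indices ``i*s .. i*s + L`` occupied at ``iteration``."""
        p = self.params
        if not (0 <= iteration < p.iters_per_epoch):
            raise IndexError(
                f"iteration {iteration} outside epoch schedule "
                f"[0, {p.iters_per_epoch}); call branch_epoch() to start "
                "the next epoch"
            )
        start = iteration * p.shift
        return np.arange(start, start + p.window_len + 1)

    def active_points(self, iteration: int) -> tuple[np.ndarray, np.ndarray]:
        """Fiber points occupied at ``iteration``, wrapped into the layer.

        Returns ``(fiber_ids, points)`` where ``points`` has shape
        ``(n_fibers * (L + 1), 2)`` in ``[0, 1)^2``.
        """
        idx = self.window_indices(iteration)
        pts = np.concatenate([path[idx] for path in self._paths], axis=0)
        ids = np.repeat(np.arange(self.params.n_fibers), idx.size)
        return ids, wrap_periodic(pts)

    def active_points_unwrapped(self, iteration: int) -> np.ndarray:
        """Raw (unwrapped) window points, shape ``(n_fibers, L + 1, 2)``."""
        idx = self.window_indices(iteration)
        return np.stack([path[idx] for path in self._paths], axis=0)

    def branch_epoch(self) -> "FiberSet":
        """Branch every fiber and advance to the next epoch.

        Each new backing path starts at a point chosen uniformly among the
        ``L + 1`` points of the fiber's final window; the old path is
        discarded.  Returns ``self`` for chaining.
        """
        last = self.window_indices(self.params.iters_per_epoch - 1)
        for k, rng in enumerate(self._rngs):
            branch_at = last[rng.integers(0, last.size)]
            origin = self._paths[k][branch_at]
            self._paths[k] = self._grow_path(origin, rng)
        self.epoch_index += 1
        return self

    def points_dataframe(self, iteration: int) -> pd.DataFrame:
        ids, pts = self.active_points(iteration)
        return pd.DataFrame(
            {
                "iteration": iteration,
                "fiber_id": ids,
                "x": pts[:, 0],
                "y": pts[:, 1],
            }
        )


def init_fibers(params: FiberParams, seed) -> FiberSet:
    """Initialize ``params.n_fibers`` independent fibers.

    Each fiber gets a fresh 2-D FBM backing path whose origin is uniform in
    the unit square; fully reproducible under ``seed``.
    """
    return FiberSet(params, seed)
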