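"""Exact simulation of fractional Brownian motion (FBM).

Fractional Brownian motion :math:`B_H(t)` is the mean-zero Gaussian process
with covariance

.. math::

    \\operatorname{Cov}(B_H(s), B_H(t))
        = \\frac{\\sigma^2}{2}\\left(s^{2H} + t^{2H} - |s-t|^{2H}\\right),

where the Hurst index :math:`H \\in (0, 1)` controls the memory of the
process: increments over consecutive equal intervals have correlation
:math:`2^{2H-1} - 1`, so ``H < 0.5`` is anti-persistent (subdiffusive),
``H = 0.5`` is ordinary Brownian motion, and ``H > 0.5`` is persistent
(superdiffusive).  The marginal variance grows as a power law
:math:`\\sigma^2 t^{2H}`.

Discrete paths are sampled on a uniform time grid by generating fractional
Gaussian noise (the stationary increment process) with the Davies--Harte
circulant-embedding method, which is *exact*: the sampled vector has exactly
the target covariance.  If the circulant embedding is not non-negative
definite for a given parameter combination, the Hosking (Durbin--Levinson)
recursion is used as an exact O(n^2) fallback.

Two-dimensional paths are built from two independent one-dimensional paths
sharing the same parameters, matching the fiber model used elsewhere in this
package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


class ParameterError(ValueError):
    """Raised when a stochastic-process parameter is out of its valid range."""


@dataclass(frozen=True)
class FBMParams:
    """Parameters of a discretely sampled fractional Brownian motion.

    Parameters
    ----------
    hurst
        Hurst index ``H``, strictly between 0 and 1.
    sigma
        Scale parameter ``sigma > 0``; ``Var(B(t)) = sigma**2 * t**(2H)``.
    t_max
        Time horizon ``T`` of the sampled path.
    dt
        Uniform sampling step; the path has ``round(T/dt)`` increments.
    seed
        Optional seed used when no generator is passed to the sampling
        functions.
    """

    hurst: float
    sigma: float = 1.0
    t_max: float = 1.0
    dt: float = 1.0 / 500.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.hurst < 1.0):
            raise ParameterError(f"hurst must lie in (0, 1), got {self.hurst}")
        if not (self.sigma > 0.0):
            raise ParameterError(f"sigma must be positive, got {self.sigma}")
        if not (self.dt > 0.0):
            raise ParameterError(f"dt must be positive, got {self.dt}")
        if not (self.t_max >= self.dt):
            raise ParameterError(
                f"t_max must be at least dt, got t_max={self.t_max}, dt={self.dt}"
            )
        if int(round(self.t_max / self.dt)) < 1:
            raise ParameterError("t_max/dt must round to a positive step count")

    @property
    def n_steps(self) -> int:
        """Number of increments in the sampled path."""
        return int(round(self.t_max / self.dt))

    @property
    def times(self) -> np.ndarray:
        """Sampling times ``0, dt, 2 dt, ..., n_steps * dt``."""
        return np.arange(self.n_steps + 1) * self.dt


@dataclass(frozen=True)
class FBMPath:
    """A realized discrete FBM path.

    ``values`` has shape ``(n_steps + 1,)`` for one-dimensional paths and
    ``(n_steps + 1, 2)`` for planar paths; index 0 is the starting point.
    """

    times: np.ndarray
    values: np.ndarray
    params: FBMParams

    @property
    def ndim(self) -> int:
        return 1 if self.values.ndim == 1 else self.values.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        cols = {"t": self.times}
        if self.ndim == 1:
            cols["x"] = self.values
        else:
            cols["x"] = self.values[:, 0]
            cols["y"] = self.values[:, 1]
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def fbm_covariance(t1: float, t2: float, params: FBMParams) -> float:
    """Closed-form covariance ``Cov(B(t1), B(t2))``.

    Returns ``(sigma**2 / 2) * (t1**2H + t2**2H - |t1 - t2|**2H)``.  Serves
    as the independent oracle against which sampled paths are validated.
    """
    if t1 < 0 or t2 < 0:
        raise ParameterError(f"times must be non-negative, got ({t1}, {t2})")
    h2 = 2.0 * params.hurst
    return 0.5 * params.sigma**2 * (t1**h2 + t2**h2 - abs(t1 - t2) ** h2)


def increment_correlation(hurst: float) -> float:
    """Correlation of FBM increments over two consecutive equal intervals.

    Equals ``2**(2H - 1) - 1``: zero at H = 0.5 (independent increments),
    positive for persistent motion, negative for anti-persistent motion.
    """
    if not (0.0 < hurst < 1.0):
        raise ParameterError(f"hurst must lie in (0, 1), got {hurst}")
    return 2.0 ** (2.0 * hurst - 1.0) - 1.0


def _fgn_autocovariance(params: FBMParams, n_lags: int) -> np.ndarray:
    """Autocovariance of fractional Gaussian noise at lags 0..n_lags-1."""
    k = np.arange(n_lags, dtype=float)
    h2 = 2.0 * params.hurst
    scale = 0.5 * params.sigma**2 * params.dt**h2
    return scale * ((k + 1.0) ** h2 - 2.0 * k**h2 + np.abs(k - 1.0) ** h2)


def _fgn_davies_harte(
    params: FBMParams, n: int, n_paths: int, rng: np.random.Generator
) -> np.ndarray | None:
    """Sample fGn by circulant embedding; None if the embedding fails."""
    gamma = _fgn_autocovariance(params, n + 1)
    # Circulant first row: gamma_0..gamma_n, gamma_{n-1}..gamma_1 (length 2n).
    circ = np.concatenate([gamma, gamma[-2:0:-1]]) if n > 1 else gamma[:1].repeat(2)
    lam = np.fft.fft(circ).real
    if lam.min() < -1e-10 * max(lam.max(), 1.0):
        return None
    lam = np.clip(lam, 0.0, None)
    m = 2 * n
    coeff = np.zeros((n_paths, m), dtype=complex)
    coeff[:, 0] = np.sqrt(lam[0] / m) * rng.standard_normal(n_paths)
    coeff[:, n] = np.sqrt(lam[n] / m) * rng.standard_normal(n_paths)
    if n > 1:
        re = rng.standard_normal((n_paths, n - 1))
        im = rng.standard_normal((n_paths, n - 1))
        coeff[:, 1:n] = np.sqrt(lam[1:n] / (2.0 * m)) * (re + 1j * im)
        coeff[:, n + 1 :] = np.conj(coeff[:, n - 1 : 0 : -1])
    return np.fft.fft(coeff, axis=1).real[:, :n]


def _fgn_hosking(
    params: FBMParams, n: int, n_paths: int, rng: np.random.Generator
) -> np.ndarray:
    """Sample fGn by the Hosking (Durbin--Levinson) recursion; exact, O(n^2)."""
    gamma = _fgn_autocovariance(params, n)
    out = np.empty((n_paths, n))
    out[:, 0] = np.sqrt(gamma[0]) * rng.standard_normal(n_paths)
    phi = np.zeros(n)
    v = gamma[0]
    for i in range(1, n):
        rho = (gamma[i] - phi[: i - 1] @ gamma[i - 1 : 0 : -1]) / v
        prev = phi[: i - 1].copy()
        phi[: i - 1] = prev - rho * prev[::-1]
        phi[i - 1] = rho
        v *= 1.0 - rho * rho
        mean = out[:, :i] @ phi[i - 1 :: -1]
        out[:, i] = mean + np.sqrt(v) * rng.standard_normal(n_paths)
    return out


def sample_fgn(
    params: FBMParams, n_paths: int, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Sample ``n_paths`` independent fractional-Gaussian-noise vectors.

    Returns an array of shape ``(n_paths, n_steps)`` whose rows are the
    increments of independent FBM paths on the grid of ``params``.
    """
    if n_paths < 1:
        raise ParameterError(f"n_paths must be positive, got {n_paths}")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    n = params.n_steps
    fgn = _fgn_davies_harte(params, n, n_paths, rng)
    if fgn is None:
        fgn = _fgn_hosking(params, n, n_paths, rng)
    return fgn


def sample_fbm_paths(
    params: FBMParams, n_paths: int, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Sample many 1-D FBM paths at once.

    Returns shape ``(n_paths, n_steps + 1)``; column 0 is identically zero
    (the process starts at the origin).  Vectorized workhorse behind
    :func:`generate_fbm_1d` and the Monte-Carlo validation suite.
    """
    fgn = sample_fgn(params, n_paths, rng)
    paths = np.empty((fgn.shape[0], fgn.shape[1] + 1))
    paths[:, 0] = 0.0
    np.cumsum(fgn, axis=1, out=paths[:, 1:])
    return paths


def generate_fbm_1d(
    params: FBMParams, rng: np.random.Generator | None = None
) -> FBMPath:
    """Generate one 1-D FBM path starting at the origin."""
    values = sample_fbm_paths(params, 1, rng)[0]
    return FBMPath(times=params.times, values=values, params=params)


def generate_fbm_2d(
    params: FBMParams,
    origin: tuple[float, float] = (0.0, 0.0),
    rng: np.random.Generator | None = None,
) -> FBMPath:
    """Generate a planar FBM path translated to start at ``origin``.

    The two coordinates are independent 1-D FBM processes with identical
    parameters, drawn from the same random stream (two distinct draws).
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    xy = sample_fbm_paths(params, 2, rng)
    values = xy.T + np.asarray(origin, dtype=float)
    return FBMPath(times=params.times, values=values, params=params)
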