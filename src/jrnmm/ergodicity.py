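"""Long-run behaviour: invariant-measure density estimation and drift checks.

With strictly positive noise on all three momentum components the model is
geometrically ergodic: it converges exponentially fast, from any initial
state, to a unique invariant measure.  Practically this means (i) the initial
value is forgotten, (ii) time averages along a single long path estimate
stationary expectations, and (iii) the stationary density of the output
signal ``Y = X1 - X2`` can be read off a single long simulation by kernel
density estimation.  This module provides those estimators plus an empirical
check of the discrete Lyapunov (drift) condition that certifies the same
behaviour for the splitting integrators.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from typing import Callable, Optional, Union

import numpy as np
from scipy.signal import find_peaks

from .integrators import simulate
from .model import InputSpec, ModelParameters, lyapunov

__all__ = [
    "LongRunSample",
    "DensityEstimate",
    "DriftCheckReport",
    "long_run",
    "kde_density",
    "time_average",
    "drift_check",
    "count_modes",
    "l1_distance",
]


@dataclass
class LongRunSample:
    """Post-burn-in, subsampled states from one long trajectory."""

    t: np.ndarray
    states: np.ndarray
    scheme: str
    seed: Optional[int]
    dt: float
    burn_in: float
    stride: int
    params: ModelParameters
    inputs: InputSpec

    @property
    def y(self) -> np.ndarray:
        return self.states[:, 1] - self.states[:, 2]

    @property
    def n_effective(self) -> int:
        return self.states.shape[0]


def long_run(
    scheme: str,
    params: ModelParameters,
    inputs: InputSpec,
    T: float,
    dt: float,
    burn_in: float = 10.0,
    stride: int = 10,
    seed: Optional[int] = None,
    x0=None,
) -> LongRunSample:
    """Simulate one long path and return post-burn-in, strided samples.

    ``burn_in`` seconds are discarded so the samples approximate the
    invariant measure; ``stride`` thins the remaining grid points to reduce
    autocorrelation.  Warns when some noise scale vanishes, since uniqueness
    of the invariant measure is only guaranteed for strictly positive noise
    on all momentum components.
    """
    if burn_in >= T:
        raise ValueError("burn_in must be smaller than T")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if not inputs.fully_elliptic:
        warnings.warn(
            "some noise scale is zero or time-dependent: the invariant measure "
            "may not be unique and long-run samples can depend on the initial value",
            stacklevel=2,
        )
    x0 = np.zeros(6) if x0 is None else np.asarray(x0, dtype=float)
    traj = simulate(scheme, x0, T, dt, seed, params, inputs)
    start = int(round(burn_in / dt))
    sel = slice(start, None, stride)
    return LongRunSample(
        t=traj.t[sel],
        states=traj.states[sel],
        scheme=scheme,
        seed=seed,
        dt=dt,
        burn_in=burn_in,
        stride=stride,
        params=params,
        inputs=inputs,
    )


# ---------------------------------------------------------------------------
# kernel density estimation
# ---------------------------------------------------------------------------


@dataclass
class DensityEstimate:
    """Gaussian-kernel density of a scalar sample on a fixed grid."""

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float
    n: int
    burn_in: Optional[float] = None
    stride: Optional[int] = None

    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.grid))

    def to_json_meta(self) -> dict:
        return {
            "schema_version": 1,
            "bandwidth": float(self.bandwidth),
            "n": int(self.n),
            "burn_in": self.burn_in,
            "stride": self.stride,
            "modes": count_modes(self),
        }


def _silverman(x: np.ndarray) -> float:
    sd = float(x.std(ddof=1))
    iqr = float(np.subtract(*np.percentile(x, [75, 25])))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    if spread <= 0:
        raise ValueError("samples have zero variance; supply an explicit bandwidth")
    return 0.9 * spread * len(x) ** (-0.2)


def kde_density(
    samples,
    grid=None,
    bandwidth: Optional[float] = None,
    *,
    n_grid: int = 512,
) -> DensityEstimate:
    """Gaussian-kernel density estimate of a scalar sample.

    The default bandwidth is Silverman's rule of thumb
    ``0.9 min(sd, IQR/1.34) n^{-1/5}``; the default grid extends four
    bandwidths beyond the sample range.  Bandwidths are absolute (same units
    as the samples).
    """
    x = np.asarray(samples, dtype=float).ravel()
    if x.size < 100:
        raise ValueError("kernel density estimation needs at least 100 samples")
    h = float(bandwidth) if bandwidth is not None else _silverman(x)
    if h <= 0:
        raise ValueError("bandwidth must be positive")
    if grid is None:
        grid = np.linspace(x.min() - 4 * h, x.max() + 4 * h, n_grid)
    else:
        grid = np.asarray(grid, dtype=float)

    dens = np.empty_like(grid)
    chunk = max(1, int(4e6) // x.size)
    c = 1.0 / (h * math.sqrt(2.0 * math.pi))
    for start in range(0, grid.size, chunk):
        g = grid[start : start + chunk]
        z = (g[:, None] - x[None, :]) / h
        dens[start : start + chunk] = c * np.exp(-0.5 * z**2).mean(axis=1)
    return DensityEstimate(grid=grid, density=dens, bandwidth=h, n=int(x.size))


def count_modes(estimate: Union[DensityEstimate, np.ndarray], rel_height: float = 0.05) -> int:
    """Number of density modes above ``rel_height`` of the global maximum."""
    d = estimate.density if isinstance(estimate, DensityEstimate) else np.asarray(estimate)
    peaks, _ = find_peaks(d, height=rel_height * float(d.max()))
    return int(len(peaks))


def l1_distance(a: DensityEstimate, b: DensityEstimate) -> float:
    """L1 distance between two density estimates (0 outside their grids)."""
    grid = np.union1d(a.grid, b.grid)
    fa = np.interp(grid, a.grid, a.density, left=0.0, right=0.0)
    fb = np.interp(grid, b.grid, b.density, left=0.0, right=0.0)
    return float(np.trapezoid(np.abs(fa - fb), grid))


# ---------------------------------------------------------------------------
# ergodic averages and drift condition
# ---------------------------------------------------------------------------


def time_average(
    h: Callable[[np.ndarray], np.ndarray],
    sample: Union[LongRunSample, np.ndarray],
    n_batches: int = 20,
):
    """Ergodic time average of ``h`` with a batch-means standard error.

    ``h`` receives the full ``(m, 6)`` state array and must return ``m``
    values.  The standard error comes from the spread of ``n_batches``
    contiguous batch means, which absorbs the autocorrelation of the path as
    long as batches are much longer than the correlation time.
    """
    states = sample.states if isinstance(sample, LongRunSample) else np.asarray(sample)
    values = np.asarray(h(states), dtype=float)
    if values.shape != (states.shape[0],):
        raise ValueError("h must map the (m, 6) state array to m scalar values")
    est = float(values.mean())
    batches = np.array_split(values, n_batches)
    means = np.array([b.mean() for b in batches])
    se = float(means.std(ddof=1) / math.sqrt(len(means)))
    return est, se


@dataclass
class DriftCheckReport:
    """Fitted one-step conditional drift of the Lyapunov functional.

    ``slope < 1`` confirms the discrete drift condition
    ``E[V(X_{i+1}) | X_i] <= alpha V(X_i) + beta`` empirically.
    """

    slope: float
    intercept: float
    dt: float
    n_transitions: int
    scheme: str
    seed: Optional[int]
    stepsize_ok: bool
    contractive: bool

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "slope": self.slope,
            "intercept": self.intercept,
            "dt": self.dt,
            "n_transitions": self.n_transitions,
            "scheme": self.scheme,
            "seed": self.seed,
            "stepsize_ok": self.stepsize_ok,
            "contractive": self.contractive,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def drift_check(
    scheme: str,
    params: ModelParameters,
    inputs: InputSpec,
    dt: float,
    n_transitions: int = 50_000,
    seed: Optional[int] = None,
    x0=None,
    n_bins: int = 20,
) -> DriftCheckReport:
    """Estimate the one-step conditional drift of ``V_1`` along a long run.

    Transitions ``(V_1(X_i), V_1(X_{i+1}))`` are grouped into ``n_bins``
    equal-count bins on the first coordinate; a least-squares line through
    the bin means estimates the conditional expectation.  The drift condition
    holds under the step-size restriction ``dt < 1/(2 max(a, b))``; for
    larger steps the report flags the hypothesis violation but still returns
    the fit.
    """
    if n_transitions < 10_000:
        raise ValueError("need at least 10000 transitions for a stable drift estimate")
    x0 = np.zeros(6) if x0 is None else np.asarray(x0, dtype=float)
    traj = simulate(scheme, x0, n_transitions * dt, dt, seed, params, inputs)
    V = lyapunov(traj.Q, traj.P, 1, params)
    v0, v1 = V[:-1], V[1:]

    order = np.argsort(v0, kind="stable")
    xm = np.empty(n_bins)
    ym = np.empty(n_bins)
    for k, idx in enumerate(np.array_split(order, n_bins)):
        xm[k] = v0[idx].mean()
        ym[k] = v1[idx].mean()
    slope, intercept = np.polyfit(xm, ym, 1)
    return DriftCheckReport(
        slope=float(slope),
        intercept=float(intercept),
        dt=float(dt),
        n_transitions=int(n_transitions),
        scheme=scheme,
        seed=seed,
        stepsize_ok=bool(dt < 1.0 / (2.0 * max(params.a, params.b))),
        contractive=bool(slope < 1.0),
    )
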