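"""Analytic moment envelopes, pathwise escape bounds and noise calibration.

All results exploit the convolution representation of the ``Q`` component::

    Q(t) = theta(t) Q0 + kappa(t) P0                      (free decay, u(t))
         + int_0^t kappa(t-s) G(s, Q(s)) ds               (forced part)
         + int_0^t kappa(t-s) Sigma dW(s)                 (Gaussian part)

Since the sigmoid is bounded, the displacement satisfies ``0 <= G <= C_G``
componentwise, which yields computable envelopes for the first and second
moments and a dominating Gaussian process for single paths.  The dominating
Gaussian gives pointwise escape-probability bounds and, inverted, a
principled way to calibrate noise levels against a threshold crossing
probability.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

from .integrators import Trajectory, _gi_integral, sample_ensemble
from .model import InputSpec, ModelParameters, _gii, _kernel_diag

__all__ = [
    "forcing_bound",
    "GaussianEnvelope",
    "gaussian_envelope",
    "mean_envelope",
    "second_moment_envelope",
    "escape_bound",
    "calibrate_sigma",
    "convolution_reconstruct",
    "CoverageReport",
    "escape_coverage",
    "EnvelopeReport",
    "envelope_report",
]


def _check_mu(inputs: InputSpec) -> np.ndarray:
    mu_max = inputs.mu_max
    if not np.all(np.isfinite(mu_max)):
        raise ValueError("moment bounds require finite upper bounds on mu_i")
    if inputs.mu_constant and np.any(inputs.mu(0.0) < 0):
        raise ValueError("moment bounds assume non-negative inputs mu_i")
    return mu_max


def forcing_bound(params: ModelParameters, inputs: InputSpec) -> np.ndarray:
    """Componentwise bound ``C_G`` on the displacement.

    ``C_G = (A a (mu3_max + nu_max), A a (mu4_max + C2 nu_max),
    B b (mu5_max + C4 nu_max))``.
    """
    mu_max = _check_mu(inputs)
    coupling = params.nu_max * np.array([1.0, params.C2, params.C4])
    return params.gain * (mu_max + coupling)


def _free_decay(t, x0, params):
    x0 = np.asarray(x0, dtype=float)
    Q0, P0 = x0[..., :3], x0[..., 3:]
    th, ka, _, _ = _kernel_diag(t, params.gamma)
    return th * Q0 + ka * P0, th


def mean_envelope(t, x0, params: ModelParameters, inputs: InputSpec):
    """Componentwise envelope for ``E[Q(t)]``.

    Returns ``(lower, upper)`` with ``lower = theta(t) Q0 + kappa(t) P0`` and
    ``upper = lower + Gamma^-2 (I - theta(t)) C_G``; shapes are
    ``t.shape + (3,)``.  As ``t`` grows the envelope contracts exponentially
    to ``[0, Gamma^-2 C_G]``.
    """
    cg = forcing_bound(params, inputs)
    u, th = _free_decay(t, x0, params)
    upper = u + params.gamma ** (-2.0) * (1.0 - th) * cg
    return u, upper


def _variance_curve(t, params: ModelParameters, inputs: InputSpec) -> np.ndarray:
    """Variance of the Gaussian part, ``1/4 Gamma^-3 Sigma^2 (I + kappa theta' - theta^2)``."""
    sigma = inputs.sigma_diag
    th, ka, thp, _ = _kernel_diag(t, params.gamma)
    return 0.25 * params.gamma ** (-3.0) * sigma**2 * (1.0 + ka * thp - th**2)


@dataclass(frozen=True)
class GaussianEnvelope:
    """Mean and variance curves of the Gaussian process dominating ``Q``.

    Components are treated as independent; the variance increases
    monotonically towards its stationary value ``Gamma^-3 Sigma^2 / 4``.
    """

    t: np.ndarray
    mean: np.ndarray
    var: np.ndarray

    @property
    def sd(self) -> np.ndarray:
        return np.sqrt(self.var)


def gaussian_envelope(t, x0, params: ModelParameters, inputs: InputSpec) -> GaussianEnvelope:
    """Dominating Gaussian law for single paths of ``Q`` at time(s) ``t``."""
    if not inputs.sigma_constant:
        raise ValueError("the pathwise bound assumes a constant diffusion matrix")
    cg = forcing_bound(params, inputs)
    u, th = _free_decay(t, x0, params)
    mean = u + params.gamma ** (-2.0) * (1.0 - th) * cg
    return GaussianEnvelope(t=np.asarray(t, dtype=float), mean=mean, var=_variance_curve(t, params, inputs))


def second_moment_envelope(t, x0, params: ModelParameters, inputs: InputSpec) -> np.ndarray:
    """Upper envelope for ``E[Q(t)^2]`` componentwise (constant diffusion only).

    ``u^2 + 2 u 1+(u) Gamma^-2 (I - theta) C_G + [Gamma^-2 (I - theta) C_G +
    Gamma^-3/2 Sigma (I + kappa theta' - theta^2)^{1/2} / 2]^2`` with all
    products taken elementwise; the indicator ``1+(u)`` drops the cross term
    where the free decay is negative.  The ``t -> infinity`` limit is
    ``(Gamma^-2 C_G + Gamma^-3/2 Sigma / 2)^2``.
    """
    if not inputs.sigma_constant:
        raise ValueError("the second-moment envelope assumes a constant diffusion matrix")
    cg = forcing_bound(params, inputs)
    sigma = inputs.sigma_diag
    g = params.gamma
    u, th = _free_decay(t, x0, params)
    _, ka, thp, _ = _kernel_diag(t, g)
    forced = g ** (-2.0) * (1.0 - th) * cg
    noise = 0.5 * g ** (-1.5) * sigma * np.sqrt(np.clip(1.0 + ka * thp - th**2, 0.0, None))
    return u**2 + 2.0 * u * (u > 0) * forced + (forced + noise) ** 2


def escape_bound(t, component: int, x_th, x0, params: ModelParameters, inputs: InputSpec):
    """Upper bound on ``P(X_component(t) >= x_th)`` from the dominating Gaussian.

    ``component`` indexes the potentials ``(x0, x1, x2)``.  With zero noise on
    that component the Gaussian degenerates and the bound is the indicator
    ``1{mean >= x_th}`` (returned as 0.0 or 1.0).
    """
    if component not in (0, 1, 2):
        raise ValueError("component must be 0, 1 or 2")
    env = gaussian_envelope(t, x0, params, inputs)
    m = env.mean[..., component]
    sd = env.sd[..., component]
    x_th = np.asarray(x_th, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(sd > 0, norm.sf((x_th - m) / np.where(sd > 0, sd, 1.0)), (m >= x_th) * 1.0)
    return out[()] if out.ndim == 0 else out


def calibrate_sigma(
    component: int,
    t: float,
    threshold: float,
    alpha: float,
    params: ModelParameters,
    inputs: InputSpec,
    x0=None,
    sigma_max: float = 1e7,
) -> float:
    """Noise scale keeping ``X_component(t)`` below ``threshold`` with confidence ``alpha``.

    Solves ``F_{Y(t)}(threshold) = alpha`` for the noise scale ``sigma`` of
    the selected component, where ``Y`` is the dominating Gaussian; the root
    is bracketed and bisected (Brent) to 1e-10 relative tolerance.  The
    threshold must lie above the envelope mean; for ``alpha = 0.5`` with the
    threshold exactly at the mean every ``sigma`` qualifies and 0.0 is
    returned by convention.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if component not in (0, 1, 2):
        raise ValueError("component must be 0, 1 or 2")
    x0 = np.zeros(6) if x0 is None else np.asarray(x0, dtype=float)
    env = gaussian_envelope(t, x0, params, inputs.with_sigma([1.0, 1.0, 1.0]))
    m = float(env.mean[..., component])
    c = float(env.sd[..., component])  # sd per unit sigma
    if np.isclose(threshold, m):
        if np.isclose(alpha, 0.5):
            return 0.0
        raise ValueError("threshold equals the envelope mean; only alpha = 0.5 is attainable")
    if threshold < m:
        raise ValueError(
            f"threshold {threshold} lies below the envelope mean {m:.6g}; no noise "
            "level can satisfy the confidence requirement"
        )

    def gap(sigma):
        return norm.cdf((threshold - m) / (sigma * c)) - alpha

    lo = 1e-12
    if gap(sigma_max) > 0:
        raise ValueError(
            f"no root in (0, {sigma_max:g}]: F({sigma_max:g}) = "
            f"{gap(sigma_max) + alpha:.6g} > alpha = {alpha}; alpha <= 0.5 is "
            "unattainable for thresholds above the mean"
        )
    return float(brentq(gap, lo, sigma_max, xtol=1e-300, rtol=1e-10))


# ---------------------------------------------------------------------------
# convolution-based reconstruction (independent oracle)
# ---------------------------------------------------------------------------


def convolution_reconstruct(traj: Trajectory) -> np.ndarray:
    """Reconstruct the ``Q`` path from the convolution representation.

    Uses the left-endpoint rectangle rule on the trajectory's own grid::

        Q(t_i) ~= theta(t_i) Q0 + kappa(t_i) P0
                  + sum_{k<i} kappa(t_i - t_k) [G(t_k, Q_k) dt + Sigma dW_k]

    For the Wiener splitting this is an exact algebraic identity; for other
    schemes the discrepancy vanishes at first order in ``dt``, which makes
    the reconstruction an independent oracle for the steppers.  Requires a
    trajectory simulated with ``record_increments=True``.
    """
    if traj.increments is None:
        raise ValueError("trajectory was simulated without increment logging")
    params, inputs = traj.params, traj.inputs
    t = traj.t
    dt = traj.dt
    n = len(t) - 1
    Q = traj.Q
    x0 = traj.states[0]
    u, _ = _free_decay(t, x0, params)

    # per-step kick: dt G^II(Q_k) + int G^I + Sigma dW_k, at left endpoints
    kick = dt * _gii(Q[:-1], params) + np.stack(
        [_gi_integral(tk, dt, params, inputs) for tk in t[:-1]]
    )
    kick = kick + inputs.sigma(t[:-1]) * traj.increments

    lags = t[:, None] - t[None, :-1]
    mask = lags > 0
    rec = u.copy()
    for c in range(3):
        g = params.gamma[c]
        K = np.where(mask, np.exp(-g * lags) * lags, 0.0)
        rec[:, c] += K @ kick[:, c]
    return rec


# ---------------------------------------------------------------------------
# Monte-Carlo reports
# ---------------------------------------------------------------------------


@dataclass
class CoverageReport:
    """Empirical coverage of the Gaussian escape-bound curves."""

    t: np.ndarray
    component: int
    alphas: np.ndarray
    curves: np.ndarray  # (n_times, n_alphas) quantile curves
    fraction_below: np.ndarray  # (n_times, n_alphas)
    se: np.ndarray
    n_paths: int

    def min_coverage(self) -> np.ndarray:
        """Worst-case (over the grid) fraction below each curve."""
        return self.fraction_below.min(axis=0)

    def to_frame(self) -> pd.DataFrame:
        data = {"t": self.t}
        for j, a in enumerate(self.alphas):
            tag = f"{a:g}"
            data[f"bound_{tag}"] = self.curves[:, j]
            data[f"coverage_{tag}"] = self.fraction_below[:, j]
            data[f"se_{tag}"] = self.se[:, j]
        return pd.DataFrame(data)


def escape_coverage(
    t_grid: Sequence[float],
    alphas: Sequence[float],
    component: int,
    x0,
    params: ModelParameters,
    inputs: InputSpec,
    *,
    scheme: str = "wiener",
    dt: float = 1e-3,
    n_paths: int = 2000,
    seed: Optional[int] = None,
) -> CoverageReport:
    """Check the pathwise bounds by simulation.

    Simulates ``n_paths`` paths and measures, at each grid time, the fraction
    lying below the ``alpha``-level quantile curve of the dominating
    Gaussian.  The bound guarantees a fraction of at least ``alpha``.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    alphas = np.asarray(alphas, dtype=float)
    T = float(t_grid.max())
    times, states = sample_ensemble(
        scheme, x0, T, dt, n_paths, seed, params, inputs, record_times=t_grid
    )
    env = gaussian_envelope(times, x0, params, inputs)
    z = norm.ppf(alphas)
    curves = env.mean[:, component, None] + z[None, :] * env.sd[:, component, None]
    below = states[:, :, component, None] < curves[None, :, :]
    frac = below.mean(axis=0)
    se = np.sqrt(frac * (1.0 - frac) / n_paths)
    return CoverageReport(
        t=times,
        component=component,
        alphas=alphas,
        curves=curves,
        fraction_below=frac,
        se=se,
        n_paths=n_paths,
    )


@dataclass
class EnvelopeReport:
    """Theoretical envelopes next to Monte-Carlo moment estimates."""

    t: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    second_moment_upper: np.ndarray
    mc_mean: np.ndarray
    mc_se: np.ndarray
    mc_sq_mean: np.ndarray
    mc_sq_se: np.ndarray
    n_paths: int

    def to_frame(self) -> pd.DataFrame:
        data = {"t": self.t}
        for c in range(3):
            data[f"lower_{c}"] = self.lower[:, c]
            data[f"upper_{c}"] = self.upper[:, c]
            data[f"mc_mean_{c}"] = self.mc_mean[:, c]
            data[f"mc_se_{c}"] = self.mc_se[:, c]
            data[f"sq_upper_{c}"] = self.second_moment_upper[:, c]
            data[f"mc_sq_mean_{c}"] = self.mc_sq_mean[:, c]
            data[f"mc_sq_se_{c}"] = self.mc_sq_se[:, c]
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.10g")


def envelope_report(
    t_grid: Sequence[float],
    x0,
    params: ModelParameters,
    inputs: InputSpec,
    *,
    scheme: str = "ou",
    dt: float = 1e-3,
    n_paths: int = 2000,
    seed: Optional[int] = None,
) -> EnvelopeReport:
    """Moment envelopes with matching Monte-Carlo estimates on a time grid."""
    t_grid = np.asarray(t_grid, dtype=float)
    lower, upper = mean_envelope(t_grid, x0, params, inputs)
    sq_upper = second_moment_envelope(t_grid, x0, params, inputs)
    T = float(t_grid.max())
    times, states = sample_ensemble(
        scheme, x0, T, dt, n_paths, seed, params, inputs, record_times=t_grid
    )
    Qs = states[:, :, :3]
    mc_mean = Qs.mean(axis=0)
    mc_se = Qs.std(axis=0, ddof=1) / np.sqrt(n_paths)
    mc_sq = (Qs**2).mean(axis=0)
    mc_sq_se = (Qs**2).std(axis=0, ddof=1) / np.sqrt(n_paths)
    return EnvelopeReport(
        t=times,
        lower=lower,
        upper=upper,
        second_moment_upper=sq_upper,
        mc_mean=mc_mean,
        mc_se=mc_se,
        mc_sq_mean=mc_sq,
        mc_sq_se=mc_sq_se,
        n_paths=n_paths,
    )
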