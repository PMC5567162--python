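"""One-step maps and trajectory drivers for the stochastic Jansen-Rit model.

Four schemes are provided, all advancing the state ``X = (Q, P)`` over a step
``dt``:

``ou``
    Lie-Trotter splitting whose stochastic sub-flow is the exact
    Ornstein-Uhlenbeck transition: the nonlinear kick ``P += dt G^II(Q) +
    int G^I`` is followed by ``X <- e^{M dt} X + xi`` with ``xi ~ N(0,
    Cov(dt))`` sampled from the exact transition covariance.
``wiener``
    Lie-Trotter splitting whose stochastic sub-flow is a Wiener process with
    drift: the kick additionally receives ``Sigma dW``, the linear flow is
    the deterministic ``e^{M dt}``.
``strang``
    Symmetric composition: half a linear flow, the full stochastic kick,
    half a linear flow.  Deterministically second order; mean-square order
    one like the Lie-Trotter maps.
``em``
    Euler-Maruyama, as the standard baseline.

All steppers are vectorised over a leading path axis, which is what makes
ensemble moment checks and the mean-square convergence study affordable.
Randomness: three Wiener components are driven by three child streams of a
single seed; the OU scheme's correlated 6-dimensional increments use a
fourth child stream.  Two runs with the same seed are bit-identical.
"""

from __future__ import annotations

import functools
import json
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import (
    InputSpec,
    ModelParameters,
    _gii,
    _kernel_diag,
    drift as model_drift,
    drift_matrix,
)

__all__ = [
    "SCHEMES",
    "OUStepCovariance",
    "Trajectory",
    "ConvergenceReport",
    "ou_step_covariance",
    "step_ou",
    "step_wiener",
    "step_strang",
    "step_em",
    "simulate",
    "sample_ensemble",
    "estimate_ms_order",
]

SCHEMES = ("ou", "wiener", "strang", "em")

_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(5)


def _gi_integral(t: float, dt: float, params: ModelParameters, inputs: InputSpec) -> np.ndarray:
    """Exact/quadrature value of ``int_t^{t+dt} G^I(s) ds`` (3-vector).

    Constant inputs integrate exactly to ``gain * mu * dt``; time-dependent
    inputs use 5-point Gauss-Legendre quadrature on the step.
    """
    if inputs.mu_constant:
        return params.gain * inputs.mu(t) * dt
    s = t + 0.5 * dt * (_GL_NODES + 1.0)
    w = 0.5 * dt * _GL_WEIGHTS
    return params.gain * np.tensordot(w, inputs.mu(s), axes=1)


def _sigma_step_scale(t: float, dt: float, inputs: InputSpec) -> np.ndarray:
    """Effective diffusion ``sqrt(int_t^{t+dt} sigma^2 ds / dt)`` per component."""
    if inputs.sigma_constant:
        return inputs.sigma_diag
    s = t + 0.5 * dt * (_GL_NODES + 1.0)
    w = 0.5 * dt * _GL_WEIGHTS
    var = np.tensordot(w, inputs.sigma(s) ** 2, axes=1)
    return np.sqrt(var / dt)


# ---------------------------------------------------------------------------
# OU transition covariance
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OUStepCovariance:
    """Exact transition covariance of the linear+noise sub-flow over ``dt``.

    ``cov`` is the 6x6 covariance of ``int_0^dt e^{M(dt-s)} S(s) dW(s)``;
    ``closed_form`` records whether the constant-diffusion closed form or the
    numerically integrated matrix ODE produced it.
    """

    dt: float
    cov: np.ndarray
    closed_form: bool

    def factor(self, tol: float = 1e-12) -> np.ndarray:
        """Symmetric square root via eigendecomposition.

        Eigenvalues in ``[-tol * ||cov||, 0)`` are clipped to zero (the
        Q-block is singular in the ``dt -> 0`` limit); anything more negative
        raises, since it signals a genuinely non-PSD matrix.
        """
        w, V = np.linalg.eigh(self.cov)
        scale = max(w.max(), 0.0)
        if w.min() < -tol * max(scale, 1.0):
            raise np.linalg.LinAlgError(
                f"OU covariance is not positive semidefinite (min eig {w.min():.3e})"
            )
        return V * np.sqrt(np.clip(w, 0.0, None))


def _ou_cov_closed_form(dt: float, params: ModelParameters, sigma: np.ndarray) -> np.ndarray:
    g = params.gamma
    th, ka, thp, kap = _kernel_diag(float(dt), g)
    common = 1.0 + ka * thp - th**2
    cqq = 0.25 * g ** (-3.0) * sigma**2 * common
    cqp = 0.5 * sigma**2 * ka**2
    cpp = 0.25 * g ** (-1.0) * sigma**2 * (1.0 + ka * thp - kap**2)
    cov = np.zeros((6, 6))
    cov[:3, :3] = np.diag(cqq)
    cov[:3, 3:] = np.diag(cqp)
    cov[3:, :3] = np.diag(cqp)
    cov[3:, 3:] = np.diag(cpp)
    return cov


def _ou_cov_ode(
    dt: float, params: ModelParameters, inputs: InputSpec, substeps: int, t0: float
) -> np.ndarray:
    """Integrate ``C' = M C + C M^T + diag(0, Sigma^2(t))`` with fixed-step RK4."""
    M = drift_matrix(params)

    def rhs(t, C):
        D = np.zeros((6, 6))
        D[3:, 3:] = np.diag(inputs.sigma(t) ** 2)
        return M @ C + C @ M.T + D

    h = dt / substeps
    C = np.zeros((6, 6))
    t = t0
    for _ in range(substeps):
        k1 = rhs(t, C)
        k2 = rhs(t + 0.5 * h, C + 0.5 * h * k1)
        k3 = rhs(t + 0.5 * h, C + 0.5 * h * k2)
        k4 = rhs(t + h, C + h * k3)
        C = C + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        t += h
    return 0.5 * (C + C.T)


@functools.lru_cache(maxsize=128)
def _ou_step_covariance_cached(
    dt: float,
    params: ModelParameters,
    inputs: InputSpec,
    closed_form: bool,
    substeps: int,
    t0: float,
) -> OUStepCovariance:
    if closed_form:
        cov = _ou_cov_closed_form(dt, params, inputs.sigma_diag)
    else:
        cov = _ou_cov_ode(dt, params, inputs, substeps, t0)
    return OUStepCovariance(dt=dt, cov=cov, closed_form=closed_form)


def ou_step_covariance(
    dt: float,
    params: ModelParameters,
    inputs: InputSpec,
    *,
    closed_form: Optional[bool] = None,
    substeps: int = 100,
    t0: float = 0.0,
) -> OUStepCovariance:
    """Covariance of the exact OU sub-flow increment over one step.

    For constant diffusion the closed form is used::

        Cov(dt) = [[ Gamma^-3 Sigma^2 (I + kappa theta' - theta^2) / 4 ,
                     Sigma^2 kappa^2 / 2 ],
                   [ Sigma^2 kappa^2 / 2 ,
                     Gamma^-1 Sigma^2 (I + kappa theta' - kappa'^2) / 4 ]]

    For time-dependent diffusion the matrix-valued ODE is integrated once per
    step-size with fixed-step 4th-order Runge-Kutta (``substeps`` stages) and
    the result is cached.  ``closed_form`` can force either route (used for
    cross-validation in the tests).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if closed_form is None:
        closed_form = inputs.sigma_constant
    if closed_form and not inputs.sigma_constant:
        raise ValueError("closed form requires a constant diffusion matrix")
    return _ou_step_covariance_cached(
        float(dt), params, inputs, bool(closed_form), int(substeps), float(t0)
    )


# ---------------------------------------------------------------------------
# one-step maps
# ---------------------------------------------------------------------------


class _Plan:
    """Precomputed per-(scheme, dt) quantities shared by all steps."""

    def __init__(self, scheme, dt, params, inputs, commute=False):
        if scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {scheme!r}; choose from {SCHEMES}")
        self.scheme = scheme
        self.dt = float(dt)
        self.params = params
        self.inputs = inputs
        self.commute = bool(commute)
        g = params.gamma
        self.kd = _kernel_diag(self.dt, g)
        self.kd_half = _kernel_diag(0.5 * self.dt, g)
        self.gamma = g
        self.sigma_const = inputs.sigma_constant
        if self.sigma_const:
            self.sigma = inputs.sigma_diag
        self.gi_const = inputs.mu_constant
        if self.gi_const:
            self.gi_int = _gi_integral(0.0, self.dt, params, inputs)
        if scheme == "ou":
            self.L = ou_step_covariance(self.dt, params, inputs).factor()

    def gi_integral(self, t):
        if self.gi_const:
            return self.gi_int
        return _gi_integral(t, self.dt, self.params, self.inputs)

    def sigma_eff(self, t):
        if self.sigma_const:
            return self.sigma
        return _sigma_step_scale(t, self.dt, self.inputs)


def _lin(Q, P, kd):
    th, ka, thp, kap = kd
    return th * Q + ka * P, thp * Q + kap * P


def _split_step(plan: _Plan, X, t, dW=None, xi=None):
    """Advance one step of the configured splitting scheme.

    ``dW`` are raw Brownian increments (covariance ``dt I``) for the
    wiener/strang/em kicks; ``xi`` is the exact 6-dim OU increment for the
    ``ou`` scheme.  Either may be ``None`` (treated as zero).
    """
    Q, P = X[..., :3], X[..., 3:]
    p = plan.params

    def kick(Q, P, tk):
        Pn = P + plan.dt * _gii(Q, p) + plan.gi_integral(tk)
        if plan.scheme == "wiener" or plan.scheme == "strang":
            if dW is not None:
                Pn = Pn + plan.sigma_eff(tk) * dW
        return Pn

    if plan.scheme == "strang":
        Q, P = _lin(Q, P, plan.kd_half)
        P = kick(Q, P, t)
        Q, P = _lin(Q, P, plan.kd_half)
    elif plan.scheme == "em":
        f = model_drift(t, X, p, plan.inputs)
        Xn = X + plan.dt * f
        if dW is not None:
            Xn = Xn + np.concatenate(
                [np.zeros_like(Q), plan.inputs.sigma(t) * dW], axis=-1
            )
        return Xn
    elif plan.commute:
        # linear flow first, then the kick
        Q, P = _lin(Q, P, plan.kd)
        if plan.scheme == "ou" and xi is not None:
            Q = Q + xi[..., :3]
            P = P + xi[..., 3:]
        P = kick(Q, P, t)
    else:
        # default composition: nonlinear kick acts first, linear flow second
        P = kick(Q, P, t)
        Q, P = _lin(Q, P, plan.kd)
        if plan.scheme == "ou" and xi is not None:
            Q = Q + xi[..., :3]
            P = P + xi[..., 3:]
    return np.concatenate([Q, P], axis=-1)


def _public_step(scheme, state, t, dt, draws, params, inputs, commute):
    state = np.asarray(state, dtype=float)
    plan = _Plan(scheme, dt, params, inputs, commute=commute)
    dW = xi = None
    if draws is not None:
        draws = np.asarray(draws, dtype=float)
        if scheme == "ou":
            xi = draws @ plan.L.T
        else:
            dW = math.sqrt(dt) * draws
    return _split_step(plan, state, float(t), dW=dW, xi=xi)


def step_ou(state, t, dt, draws=None, *, params, inputs, commute=False):
    """One step of the Ornstein-Uhlenbeck splitting.

    ``draws`` are 6 standard normal variates (``None`` for the deterministic
    map); they are coloured by the exact transition covariance internally.
    """
    return _public_step("ou", state, t, dt, draws, params, inputs, commute)


def step_wiener(state, t, dt, draws=None, *, params, inputs, commute=False):
    """One step of the Wiener splitting (``draws``: 3 standard normals)."""
    return _public_step("wiener", state, t, dt, draws, params, inputs, commute)


def step_strang(state, t, dt, draws=None, *, params, inputs, commute=False):
    """One Strang step: half linear flow, stochastic kick, half linear flow."""
    return _public_step("strang", state, t, dt, draws, params, inputs, commute)


def step_em(state, t, dt, draws=None, *, params, inputs, commute=False):
    """One Euler-Maruyama step ``X + f(t, X) dt + S(t) dW``."""
    return _public_step("em", state, t, dt, draws, params, inputs, commute)


# ---------------------------------------------------------------------------
# trajectory drivers
# ---------------------------------------------------------------------------


@dataclass
class Trajectory:
    """A simulated path on an equidistant grid.

    ``states`` has shape ``(N+1, 6)`` ordered ``(x0 .. x5) = (Q, P)``; the
    output signal is ``y = x1 - x2``.  ``increments`` holds the raw Brownian
    increments (shape ``(N, 3)``) when increment logging was requested.
    """

    t: np.ndarray
    states: np.ndarray
    scheme: str
    seed: Optional[int]
    params: ModelParameters
    inputs: InputSpec
    increments: Optional[np.ndarray] = None

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def Q(self) -> np.ndarray:
        return self.states[..., :3]

    @property
    def P(self) -> np.ndarray:
        return self.states[..., 3:]

    @property
    def y(self) -> np.ndarray:
        return self.states[..., 1] - self.states[..., 2]

    def to_frame(self) -> pd.DataFrame:
        cols = {f"x{i}": self.states[:, i] for i in range(6)}
        return pd.DataFrame({"t": self.t, **cols, "y": self.y})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.12g")


def _streams(seed):
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(c) for c in ss.spawn(4)]


def _needs_dw(scheme):
    return scheme in ("wiener", "strang", "em")


def _run(
    scheme,
    x0,
    T,
    dt,
    seed,
    params,
    inputs,
    *,
    n_paths=None,
    record_idx=None,
    record_increments=False,
    commute=False,
):
    """Shared driver; returns (t_nodes, recorded states, increments)."""
    if T <= 0 or dt <= 0:
        raise ValueError("T and dt must be positive")
    n_steps = int(round(T / dt))
    if abs(n_steps * dt - T) > 1e-9 * max(T, 1.0):
        raise ValueError("T must be an integral multiple of dt (within rounding)")
    x0 = np.asarray(x0, dtype=float)
    single = x0.ndim == 1 and n_paths is None
    n = 1 if single else (n_paths if x0.ndim == 1 else x0.shape[0])
    X = np.broadcast_to(x0, (n, 6)).copy()

    plan = _Plan(scheme, dt, params, inputs, commute=commute)
    rngs = _streams(seed)
    sqdt = math.sqrt(dt)
    noisy = _needs_dw(scheme) and not (
        inputs.sigma_constant and np.all(inputs.sigma_diag == 0.0)
    )
    ou_noisy = scheme == "ou" and not (
        inputs.sigma_constant and np.all(inputs.sigma_diag == 0.0)
    )
    if record_increments and scheme == "ou":
        raise ValueError(
            "increment logging stores Brownian increments, which the ou scheme "
            "does not use; simulate with the wiener/strang/em schemes instead"
        )

    record_all = record_idx is None
    if record_all:
        out = np.empty((n_steps + 1, n, 6))
        out[0] = X
    else:
        record_idx = np.asarray(record_idx, dtype=int)
        out = np.empty((len(record_idx), n, 6))
        pos = {int(i): k for k, i in enumerate(record_idx)}
        if 0 in pos:
            out[pos[0]] = X
    incs = np.empty((n_steps, n, 3)) if record_increments else None

    t = 0.0
    for i in range(n_steps):
        dW = xi = None
        if _needs_dw(scheme) and (noisy or record_increments):
            dW = sqdt * np.stack(
                [rngs[k].standard_normal(n) for k in range(3)], axis=-1
            )
        if ou_noisy:
            xi = rngs[3].standard_normal((n, 6)) @ plan.L.T
        X = _split_step(plan, X, t, dW=dW, xi=xi)
        if not np.all(np.isfinite(X)):
            raise FloatingPointError(f"non-finite state encountered at step {i + 1}")
        if incs is not None:
            incs[i] = dW if dW is not None else 0.0
        t = (i + 1) * dt
        if record_all:
            out[i + 1] = X
        elif (i + 1) in pos:
            out[pos[i + 1]] = X

    t_nodes = dt * np.arange(n_steps + 1)
    if single:
        out = out[:, 0, :]
        if incs is not None:
            incs = incs[:, 0, :]
    return t_nodes, out, incs


def simulate(
    scheme: str,
    x0,
    T: float,
    dt: float,
    seed: Optional[int],
    params: ModelParameters,
    inputs: InputSpec,
    *,
    record_increments: bool = False,
    commute: bool = False,
) -> Trajectory:
    """Simulate a single path with the chosen one-step map.

    ``N = round(T / dt)`` steps on an equidistant grid; two calls with the
    same seed are bit-identical.  ``record_increments=True`` stores the raw
    Brownian increments so that the convolution-based representation can be
    reconstructed afterwards (wiener/strang/em schemes only).
    """
    t, states, incs = _run(
        scheme,
        x0,
        T,
        dt,
        seed,
        params,
        inputs,
        record_increments=record_increments,
        commute=commute,
    )
    return Trajectory(
        t=t,
        states=states,
        scheme=scheme,
        seed=seed,
        params=params,
        inputs=inputs,
        increments=incs,
    )


def sample_ensemble(
    scheme: str,
    x0,
    T: float,
    dt: float,
    n_paths: int,
    seed: Optional[int],
    params: ModelParameters,
    inputs: InputSpec,
    record_times: Optional[Sequence[float]] = None,
    commute: bool = False,
):
    """Simulate ``n_paths`` independent paths, recording selected grid times.

    Returns ``(times, states)`` with ``states`` of shape
    ``(n_paths, len(times), 6)``.  ``record_times`` defaults to the final
    time only; every requested time must lie on the step grid.
    """
    n_steps = int(round(T / dt))
    if record_times is None:
        idx = np.array([n_steps])
    else:
        rt = np.asarray(record_times, dtype=float)
        idx = np.round(rt / dt).astype(int)
        if np.any(np.abs(idx * dt - rt) > 1e-9 * max(T, 1.0)):
            raise ValueError("record_times must lie on the simulation grid")
    t, out, _ = _run(
        scheme,
        np.asarray(x0, dtype=float),
        T,
        dt,
        seed,
        params,
        inputs,
        n_paths=n_paths,
        record_idx=idx,
        commute=commute,
    )
    return t[idx], np.swapaxes(out, 0, 1)


# ---------------------------------------------------------------------------
# mean-square convergence order
# ---------------------------------------------------------------------------


@dataclass
class ConvergenceReport:
    """Result of a coupled-path mean-square convergence study."""

    scheme: str
    dt_list: np.ndarray
    rmse: np.ndarray
    slope: float
    slope_se: float
    n_paths: int
    seed: Optional[int]
    reference: str = "strang"

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "scheme": self.scheme,
            "dt": list(map(float, self.dt_list)),
            "rmse": list(map(float, self.rmse)),
            "slope": float(self.slope),
            "slope_se": float(self.slope_se),
            "n_paths": int(self.n_paths),
            "seed": self.seed,
            "reference": self.reference,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _run_coupled(scheme, x0s, dt, n_steps, params, inputs, dW=None, xi=None, commute=False):
    """Advance all paths with externally supplied per-step noise arrays."""
    plan = _Plan(scheme, dt, params, inputs, commute=commute)
    X = x0s.copy()
    t = 0.0
    for i in range(n_steps):
        X = _split_step(
            plan,
            X,
            t,
            dW=None if dW is None else dW[:, i, :],
            xi=None if xi is None else xi[:, i, :],
        )
        t = (i + 1) * dt
    return X


def _ou_increments_from_fine(fine, m, delta, params, sigma):
    """Riemann-sum reconstruction of the exact OU increments from fine noise.

    For a coarse step of ``m`` fine increments the stochastic convolution
    ``int e^{M(dt-s)} S dW`` is approximated at the right endpoints:
    ``xi = sum_j e^{M (m-1-j) delta} S dW_j``.  Its covariance converges to
    the exact ``Cov(dt)`` as ``delta -> 0``, so the coupling error vanishes
    faster than the first-order scheme error it is used to measure.
    """
    n, n_fine, _ = fine.shape
    n_coarse = n_fine // m
    lag = delta * (m - 1 - np.arange(m))
    th, ka, thp, kap = _kernel_diag(lag, params.gamma)  # (m, 3) each
    F = fine.reshape(n, n_coarse, m, 3) * sigma
    xi_q = np.einsum("pkjc,jc->pkc", F, ka)
    xi_p = np.einsum("pkjc,jc->pkc", F, kap)
    return np.concatenate([xi_q, xi_p], axis=-1)


def estimate_ms_order(
    scheme: str,
    params: ModelParameters,
    inputs: InputSpec,
    T: float = 1.0,
    dt_list: Sequence[float] = (4e-3, 2e-3, 1e-3, 5e-4),
    n_paths: int = 500,
    seed: Optional[int] = None,
    x0=None,
    ref_refine: int = 4,
    n_groups: int = 10,
    commute: bool = False,
) -> ConvergenceReport:
    """Measure the mean-square convergence order of a scheme.

    Coupled Brownian paths are generated on the finest grid ``dt_min /
    ref_refine`` and aggregated to each coarser grid, so every run sees the
    same noise.  The reference solution is the Strang splitting on the finest
    grid.  Errors are root-mean-square endpoint errors over ``n_paths``
    paths; the reported order is the least-squares slope of ``log(error)``
    against ``log(dt)``, with a standard error estimated from ``n_groups``
    disjoint path groups.
    """
    dts = np.asarray(sorted(dt_list, reverse=True), dtype=float)
    if len(dts) < 3:
        raise ValueError("need at least three step-sizes")
    for d in dts[1:]:
        ratio = dts[0] / d
        if abs(ratio - round(ratio)) > 1e-9 or round(ratio) & (round(ratio) - 1):
            raise ValueError("step-sizes must be dyadic refinements of the coarsest")
    if not inputs.sigma_constant:
        raise ValueError("the convergence study assumes constant diffusion")
    dt_ref = dts[-1] / ref_refine
    n_ref = int(round(T / dt_ref))
    if abs(n_ref * dt_ref - T) > 1e-12 * max(T, 1.0):
        raise ValueError("T must be a multiple of the reference step")

    sigma = inputs.sigma_diag
    deterministic = bool(np.all(sigma == 0.0))
    if deterministic:
        n_paths = 1
    x0 = np.zeros(6) if x0 is None else np.asarray(x0, dtype=float)
    x0s = np.broadcast_to(x0, (n_paths, 6)).copy()

    rngs = _streams(seed)
    fine = math.sqrt(dt_ref) * np.stack(
        [rngs[k].standard_normal((n_paths, n_ref)) for k in range(3)], axis=-1
    )

    ref = _run_coupled("strang", x0s, dt_ref, n_ref, params, inputs, dW=fine)

    rmse = np.empty(len(dts))
    group_err = np.empty((len(dts), n_groups))
    groups = np.array_split(np.arange(n_paths), n_groups)
    for j, dt in enumerate(dts):
        m = int(round(dt / dt_ref))
        n_steps = n_ref // m
        coarse = fine.reshape(n_paths, n_steps, m, 3).sum(axis=2)
        if scheme == "ou":
            xi = _ou_increments_from_fine(fine, m, dt_ref, params, sigma)
            end = _run_coupled(
                scheme, x0s, dt, n_steps, params, inputs, xi=xi, commute=commute
            )
        else:
            end = _run_coupled(
                scheme, x0s, dt, n_steps, params, inputs, dW=coarse, commute=commute
            )
        err2 = np.sum((end - ref) ** 2, axis=-1)
        rmse[j] = math.sqrt(float(err2.mean()))
        for gidx, g in enumerate(groups):
            group_err[j, gidx] = math.sqrt(float(err2[g].mean())) if len(g) else np.nan

    if np.any(rmse <= 0):
        raise ValueError("zero endpoint error; scheme coincides with the reference")
    slope = float(np.polyfit(np.log(dts), np.log(rmse), 1)[0])
    if deterministic or n_paths < n_groups:
        slope_se = 0.0
    else:
        gs = [
            float(np.polyfit(np.log(dts), np.log(group_err[:, g]), 1)[0])
            for g in range(n_groups)
        ]
        slope_se = float(np.std(gs, ddof=1) / math.sqrt(n_groups))
    return ConvergenceReport(
        scheme=scheme,
        dt_list=dts,
        rmse=rmse,
        slope=slope,
        slope_se=slope_se,
        n_paths=n_paths,
        seed=seed,
    )
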