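"""Core parameterisation of the stochastic Jansen-Rit neural mass model.

The Jansen-Rit model describes the mean activity of a cortical column through
three interacting neural populations (pyramidal cells, excitatory and
inhibitory interneurons).  Each population turns an incoming mean firing rate
into a mean postsynaptic potential through a second-order linear filter, and
turns a membrane potential back into a firing rate through a logistic sigmoid.
Collecting the three potentials in ``Q`` (mV) and their derivatives in ``P``
(mV/s), the stochastic model is a damped Hamiltonian system with additive
noise on the momentum equation::

    dQ = P dt
    dP = (-Gamma^2 Q - 2 Gamma P + G(t, Q)) dt + Sigma(t) dW

with diagonal damping ``Gamma = diag[a, a, b]``, displacement ``G`` built from
the sigmoid gain, diffusion ``Sigma = diag[sigma3, sigma4, sigma5]`` and three
independent Wiener processes.  The EEG-like output signal is
``Y = X1 - X2``, the net membrane potential of the pyramidal population.

Because the linear part has the block structure ``M = [[0, I], [-Gamma^2,
-2*Gamma]]`` with *diagonal* sub-blocks, the matrix exponential ``e^{Mt}`` is
available in closed form (see :func:`kernel_blocks`); this is what makes the
exact splitting integrators in :mod:`jrnmm.integrators` possible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, NamedTuple, Union

import numpy as np
from scipy.special import expit

__all__ = [
    "ModelParameters",
    "InputSpec",
    "TimeFunction",
    "KernelBlocks",
    "Displacement",
    "sigmoid",
    "displacement",
    "drift",
    "drift_matrix",
    "hamiltonian",
    "energy_rate",
    "kernel_blocks",
    "lyapunov",
]


@dataclass(frozen=True)
class TimeFunction:
    """A bounded deterministic function of time.

    Time-varying inputs and noise scales must declare a finite upper bound
    explicitly (``bound``), since the moment and escape bounds require
    ``mu_i <= mu_i,max``.  ``fn`` must accept numpy arrays of times.
    """

    fn: Callable[[np.ndarray], np.ndarray]
    bound: float

    def __post_init__(self):
        if not math.isfinite(self.bound):
            raise ValueError("TimeFunction bound must be finite")

    def __call__(self, t):
        return self.fn(t)


Scalar = Union[float, int]
InputValue = Union[Scalar, TimeFunction]


@dataclass(frozen=True)
class ModelParameters:
    """Physiological constants of the Jansen-Rit model.

    Defaults are the standard literature values (time constants converted to
    rate constants on the seconds scale: ``a = 100 1/s``, ``b = 50 1/s``).

    Parameters
    ----------
    A, B : float
        Average excitatory / inhibitory synaptic gain (mV).
    a, b : float
        Reciprocal time constants of the excitatory / inhibitory
        postsynaptic responses (1/s).
    C1, C2, C3, C4 : float
        Connectivity constants (average synapse counts between populations).
    nu_max : float
        Maximum population firing rate, the sigmoid plateau (1/s).
    v0 : float
        Potential at which half the maximum firing rate is reached (mV).
    r : float
        Sigmoid slope at ``v0`` (1/mV).
    """

    A: float = 3.25
    B: float = 22.0
    a: float = 100.0
    b: float = 50.0
    C1: float = 135.0
    C2: float = 108.0
    C3: float = 33.75
    C4: float = 33.75
    nu_max: float = 5.0
    v0: float = 6.0
    r: float = 0.56

    def __post_init__(self):
        if not (self.a > 0 and self.b > 0):
            raise ValueError("rate constants a, b must be positive")
        if not (self.nu_max > 0 and self.r > 0):
            raise ValueError("nu_max and r must be positive")
        for name in ("C1", "C2", "C3", "C4"):
            if getattr(self, name) < 0:
                raise ValueError(f"connectivity constant {name} must be >= 0")

    @classmethod
    def from_C(cls, C: float = 135.0, **overrides) -> "ModelParameters":
        """Build a parameter set from the single connectivity scale ``C``.

        Uses the standard proportions ``C1 = C``, ``C2 = 0.8 C``,
        ``C3 = C4 = 0.25 C``; all other fields keep their defaults unless
        overridden.
        """
        base = dict(C1=C, C2=0.8 * C, C3=0.25 * C, C4=0.25 * C)
        base.update(overrides)
        return cls(**base)

    @property
    def gamma(self) -> np.ndarray:
        """Diagonal of the damping matrix ``Gamma = diag[a, a, b]``."""
        return np.array([self.a, self.a, self.b])

    @property
    def gain(self) -> np.ndarray:
        """Row gains ``(A a, A a, B b)`` multiplying the displacement."""
        return np.array([self.A * self.a, self.A * self.a, self.B * self.b])


def _value_and_bound(v: InputValue) -> float:
    return v.bound if isinstance(v, TimeFunction) else float(v)


def _eval_input(v: InputValue, t) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if isinstance(v, TimeFunction):
        return np.broadcast_to(np.asarray(v(t), dtype=float), t.shape)
    return np.full(t.shape, float(v))


@dataclass(frozen=True)
class InputSpec:
    """Deterministic inputs and noise scales of the stochastic model.

    ``mu3, mu4, mu5`` enter the displacement as ``G^I = (A a mu3, A a mu4,
    B b mu5)``; ``sigma3, sigma4, sigma5`` are the diagonal of the diffusion
    matrix acting on ``(X3, X4, X5)``.  Each entry is either a constant or a
    :class:`TimeFunction` carrying an explicit upper bound.
    """

    mu3: InputValue = 0.0
    mu4: InputValue = 0.0
    mu5: InputValue = 0.0
    sigma3: InputValue = 0.0
    sigma4: InputValue = 0.0
    sigma5: InputValue = 0.0

    def __post_init__(self):
        for name in ("sigma3", "sigma4", "sigma5"):
            v = getattr(self, name)
            if not isinstance(v, TimeFunction) and v < 0:
                raise ValueError(f"{name} must be non-negative")

    # -- deterministic input -------------------------------------------------
    @property
    def mu_constant(self) -> bool:
        return not any(isinstance(m, TimeFunction) for m in (self.mu3, self.mu4, self.mu5))

    @property
    def mu_max(self) -> np.ndarray:
        """Componentwise upper bounds ``(mu3_max, mu4_max, mu5_max)``."""
        return np.array([_value_and_bound(m) for m in (self.mu3, self.mu4, self.mu5)])

    def mu(self, t) -> np.ndarray:
        """Evaluate ``(mu3, mu4, mu5)`` at time(s) ``t`` -> shape ``t.shape + (3,)``."""
        return np.stack([_eval_input(m, t) for m in (self.mu3, self.mu4, self.mu5)], axis=-1)

    # -- noise ---------------------------------------------------------------
    @property
    def sigma_constant(self) -> bool:
        return not any(
            isinstance(s, TimeFunction) for s in (self.sigma3, self.sigma4, self.sigma5)
        )

    @property
    def sigma_diag(self) -> np.ndarray:
        """Constant diffusion diagonal; raises for time-dependent noise."""
        if not self.sigma_constant:
            raise ValueError("diffusion matrix is time-dependent")
        return np.array([float(self.sigma3), float(self.sigma4), float(self.sigma5)])

    def sigma(self, t) -> np.ndarray:
        return np.stack(
            [_eval_input(s, t) for s in (self.sigma3, self.sigma4, self.sigma5)], axis=-1
        )

    @property
    def fully_elliptic(self) -> bool:
        """True when all noise scales are strictly positive constants.

        Uniqueness of the invariant measure (and hence geometric ergodicity)
        requires noise on every momentum component.
        """
        return self.sigma_constant and bool(np.all(self.sigma_diag > 0))

    def with_sigma(self, sigma) -> "InputSpec":
        s3, s4, s5 = np.broadcast_to(np.asarray(sigma, dtype=float), (3,))
        return replace(self, sigma3=float(s3), sigma4=float(s4), sigma5=float(s5))


# ---------------------------------------------------------------------------
# sigmoid gain and displacement
# ---------------------------------------------------------------------------

def sigmoid(x, params: ModelParameters):
    """Logistic firing-rate gain ``nu_max / (1 + exp(r (v0 - x)))``.

    Maps a mean membrane potential (mV) to a mean firing rate in
    ``(0, nu_max)``; strictly increasing, with value ``nu_max / 2`` at
    ``x = v0``.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("sigmoid argument must be finite")
    return params.nu_max * expit(params.r * (x - params.v0))


def _gii(Q: np.ndarray, p: ModelParameters) -> np.ndarray:
    """Nonlinear displacement ``G^II(Q)``, vectorised over leading axes."""
    y = Q[..., 1] - Q[..., 2]
    s = lambda x: p.nu_max * expit(p.r * (x - p.v0))  # noqa: E731 - hot path
    return np.stack(
        [
            p.A * p.a * s(y),
            p.A * p.a * p.C2 * s(p.C1 * Q[..., 0]),
            p.B * p.b * p.C4 * s(p.C3 * Q[..., 0]),
        ],
        axis=-1,
    )


class Displacement(NamedTuple):
    """Split displacement ``G = G^I(t) + G^II(Q)``."""

    gi: np.ndarray
    gii: np.ndarray

    @property
    def total(self) -> np.ndarray:
        return self.gi + self.gii


def displacement(t, Q, params: ModelParameters, inputs: InputSpec) -> Displacement:
    """Evaluate the displacement ``G(t, Q)`` split into forcing and coupling.

    ``G^I(t) = (A a mu3, A a mu4, B b mu5)`` carries the external input;
    ``G^II(Q)`` carries the sigmoid population coupling and is componentwise
    bounded by ``(A a nu_max, A a C2 nu_max, B b C4 nu_max)``.
    """
    Q = np.asarray(Q, dtype=float)
    if Q.shape[-1] != 3:
        raise ValueError("Q must have three components")
    gi = params.gain * inputs.mu(t)[..., :]
    return Displacement(gi=gi, gii=_gii(Q, params))


def drift_matrix(params: ModelParameters) -> np.ndarray:
    """Linear drift matrix ``M = [[0, I], [-Gamma^2, -2 Gamma]]`` (6x6)."""
    g = params.gamma
    M = np.zeros((6, 6))
    M[:3, 3:] = np.eye(3)
    M[3:, :3] = -np.diag(g**2)
    M[3:, 3:] = -2.0 * np.diag(g)
    return M


def drift(t, X, params: ModelParameters, inputs: InputSpec) -> np.ndarray:
    """Full drift ``f(t, X) = M X + (0, G(t, Q))`` for states of shape (..., 6)."""
    X = np.asarray(X, dtype=float)
    if X.shape[-1] != 6:
        raise ValueError("state must have six components")
    Q, P = X[..., :3], X[..., 3:]
    g = params.gamma
    G = displacement(t, Q, params, inputs).total
    dP = -(g**2) * Q - 2.0 * g * P + G
    return np.concatenate([P, dP], axis=-1)


# ---------------------------------------------------------------------------
# energy
# ---------------------------------------------------------------------------

def hamiltonian(Q, P, params: ModelParameters):
    """Total energy ``H = (||P||^2 + ||Gamma Q||^2) / 2`` of the oscillator part."""
    Q = np.asarray(Q, dtype=float)
    P = np.asarray(P, dtype=float)
    g = params.gamma
    return 0.5 * (np.sum(P**2, axis=-1) + np.sum((g * Q) ** 2, axis=-1))


def energy_rate(t, Q, P, params: ModelParameters, inputs: InputSpec):
    """Instantaneous energy change ``dH/dt = -2 P^T Gamma P + P^T G(t, Q)``.

    Along deterministic trajectories the damping term drains energy while the
    displacement pumps it; the balance produces the model's limit cycles.
    """
    Q = np.asarray(Q, dtype=float)
    P = np.asarray(P, dtype=float)
    g = params.gamma
    G = displacement(t, Q, params, inputs).total
    return -2.0 * np.sum(g * P**2, axis=-1) + np.sum(P * G, axis=-1)


# ---------------------------------------------------------------------------
# closed-form linear flow
# ---------------------------------------------------------------------------

def _kernel_diag(t, gamma: np.ndarray):
    """Diagonals of the e^{Mt} blocks, broadcast to ``t.shape + (3,)``.

    theta(t)  = e^{-Gamma t} (I + Gamma t)
    kappa(t)  = e^{-Gamma t} t
    theta'(t) = -Gamma^2 e^{-Gamma t} t
    kappa'(t) = e^{-Gamma t} (I - Gamma t)
    """
    t = np.asarray(t, dtype=float)[..., None]
    gt = gamma * t
    e = np.exp(-gt)
    theta = e * (1.0 + gt)
    kappa = e * t
    theta_p = -(gamma**2) * e * t
    kappa_p = e * (1.0 - gt)
    return theta, kappa, theta_p, kappa_p


@dataclass(frozen=True)
class KernelBlocks:
    """Evaluated blocks of ``e^{Mt}`` at a fixed time ``t``.

    The assembled 6x6 matrix is ``[[theta, kappa], [theta_prime,
    kappa_prime]]``; it satisfies the semigroup identity
    ``E(t+s) = E(t) E(s)`` and commutes with ``M``.
    """

    t: float
    Gamma: np.ndarray
    M: np.ndarray
    theta: np.ndarray
    kappa: np.ndarray
    theta_prime: np.ndarray
    kappa_prime: np.ndarray

    @property
    def expm(self) -> np.ndarray:
        """Assembled 6x6 matrix exponential ``e^{Mt}``."""
        E = np.zeros((6, 6))
        E[:3, :3] = self.theta
        E[:3, 3:] = self.kappa
        E[3:, :3] = self.theta_prime
        E[3:, 3:] = self.kappa_prime
        return E


def kernel_blocks(t: float, params: ModelParameters) -> KernelBlocks:
    """Evaluate the closed-form matrix-exponential blocks at time ``t``.

    Negative ``t`` is allowed and yields the inverse flow ``e^{-M|t|}``
    through the same formulas (sign convention: ``t`` is the elapsed time of
    the forward flow).
    """
    th, ka, thp, kap = _kernel_diag(float(t), params.gamma)
    return KernelBlocks(
        t=float(t),
        Gamma=np.diag(params.gamma),
        M=drift_matrix(params),
        theta=np.diag(th),
        kappa=np.diag(ka),
        theta_prime=np.diag(thp),
        kappa_prime=np.diag(kap),
    )


# ---------------------------------------------------------------------------
# Lyapunov functional
# ---------------------------------------------------------------------------

def lyapunov(Q, P, n: int, params: ModelParameters):
    """Lyapunov functional ``V_n = (1 + ||P||^2/2 + 3||Gamma Q||^2/2 + <P, Gamma Q>)^n``.

    For ``a, b > 0`` the quadratic part is positive definite, so ``V_n >= 1``
    and ``V_n`` is radially unbounded; its expected drift is contractive,
    which underpins geometric ergodicity of the model and of the splitting
    schemes.
    """
    if int(n) != n or n < 1:
        raise ValueError("Lyapunov power n must be a positive integer")
    Q = np.asarray(Q, dtype=float)
    P = np.asarray(P, dtype=float)
    gq = params.gamma * Q
    base = (
        1.0
        + 0.5 * np.sum(P**2, axis=-1)
        + 1.5 * np.sum(gq**2, axis=-1)
        + np.sum(P * gq, axis=-1)
    )
    return base ** int(n)
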