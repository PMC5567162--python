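"""Scenario presets for the standard simulation experiments.

Each preset bundles a connectivity scale ``C``, the external inputs and noise
scales, an initial state and default run settings.  ``alpha_C135`` is the
noisy alpha-rhythm regime (``mu = (0, 220, 0)``, ``sigma = (10, 1000, 10)``);
``phase_C135_smallnoise`` is the weak-noise phase-portrait regime
(``sigma = (1, 200, 1)``, ``X(0) = 0``).  The ``C68/C135/C270/C675`` presets
sweep the connectivity scale with the alpha-regime inputs, covering the
transition from unimodal to multimodal stationary output densities.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

from .model import InputSpec, ModelParameters

__all__ = ["ScenarioPreset", "PRESETS", "get_preset"]


@dataclass(frozen=True)
class ScenarioPreset:
    """A named, fully specified simulation scenario."""

    name: str
    C: float
    mu: Tuple[float, float, float]
    sigma: Tuple[float, float, float]
    x0: Tuple[float, float, float, float, float, float] = (0.0,) * 6
    T: float = 10.0
    dt: float = 1e-3
    scheme: str = "strang"

    def params(self) -> ModelParameters:
        return ModelParameters.from_C(self.C)

    def inputs(self) -> InputSpec:
        m, s = self.mu, self.sigma
        return InputSpec(mu3=m[0], mu4=m[1], mu5=m[2], sigma3=s[0], sigma4=s[1], sigma5=s[2])

    def initial_state(self) -> np.ndarray:
        return np.asarray(self.x0, dtype=float)


_ALPHA_MU = (0.0, 220.0, 0.0)
_ALPHA_SIGMA = (10.0, 1000.0, 10.0)

PRESETS = {
    p.name: p
    for p in (
        ScenarioPreset(name="alpha_C135", C=135.0, mu=_ALPHA_MU, sigma=_ALPHA_SIGMA),
        ScenarioPreset(
            name="phase_C135_smallnoise", C=135.0, mu=_ALPHA_MU, sigma=(1.0, 200.0, 1.0)
        ),
        ScenarioPreset(name="C68", C=68.0, mu=_ALPHA_MU, sigma=_ALPHA_SIGMA),
        ScenarioPreset(name="C135", C=135.0, mu=_ALPHA_MU, sigma=_ALPHA_SIGMA),
        ScenarioPreset(name="C270", C=270.0, mu=_ALPHA_MU, sigma=_ALPHA_SIGMA),
        ScenarioPreset(name="C675", C=675.0, mu=_ALPHA_MU, sigma=_ALPHA_SIGMA),
    )
}


def get_preset(name: str) -> ScenarioPreset:
    """Look up a preset by name; raises ``KeyError`` with the known names."""
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(sorted(PRESETS))}"
        ) from None
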