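"""Forward model: diffuse + semiballistic single-fiber reflectance.

The absorption-free single-fiber reflectance is decomposed as

.. math::

    R_0 = R_{SFR,dif} + R_{SFR,sb} = (1 + X)\\, \\eta_c\\, R_{dif}(\\mu_s' d),

with the semiballistic-to-diffuse ratio modelled as

.. math::

    X = a_2 \\left[\\frac{p_{sb}}{(\\mu_s' d)^2}\\right]^{a_3}.

The ``(mu_s' d)^2`` in the denominator matches the small-argument scaling of
the diffuse component, so X grows as scattering decreases; ``a2`` and ``a3``
are calibrated against Monte Carlo per numerical aperture, and ``a1`` (inside
``eta_c``) absorbs the non-Lambertian angular profile of returning light.

The previously published single-fiber model of Kanick et al., which
parameterizes the phase-function influence through
``gamma = (1 - g2)/(1 - g1)`` alone, is provided for comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .diffuse import ProbeConfig, collection_efficiency, diffuse_reflectance
from .phase_functions import PhaseFunction
from .subdiffuse import psb as _psb_of_model

__all__ = [
    "ModelConstants",
    "ModelPrediction",
    "ValidityWarning",
    "semiballistic_ratio",
    "predict_R0",
    "kanick_R0",
    "MUSP_D_VALIDITY_LIMIT",
]

#: Below this value of mu_s'*d the diffusion-based component is unreliable.
MUSP_D_VALIDITY_LIMIT = 0.1

#: Calibrated (a2, a3) per numerical aperture, with the shared a1 = 1.11.
_DEFAULT_A2A3 = {
    0.10: (4370.0, 0.780),
    0.22: (3046.0, 0.748),
    0.50: (1475.0, 0.688),
}


class ValidityWarning(UserWarning):
    """Emitted when the model is evaluated outside its validated range."""


@dataclass(frozen=True)
class ModelConstants:
    """Calibration constants of the semiballistic reflectance model.

    ``a1`` is shared across numerical apertures; ``(a2, a3)`` are keyed by
    NA.  The defaults are the calibrated values for NAs 0.10, 0.22, 0.50.
    Requesting an uncalibrated NA raises — constants are not interpolated.
    """

    a1: float = 1.11
    a2a3: dict = field(default_factory=lambda: dict(_DEFAULT_A2A3))

    def __post_init__(self) -> None:
        if self.a1 <= 0:
            raise ValueError("a1 must be > 0")
        for na, (a2, a3) in self.a2a3.items():
            if a2 <= 0 or a3 <= 0:
                raise ValueError(f"a2, a3 must be > 0 (NA={na})")

    def for_na(self, na: float) -> tuple[float, float, float]:
        """(a1, a2, a3) for the given NA (matched within 1e-6)."""
        for key, (a2, a3) in self.a2a3.items():
            if abs(key - na) < 1e-6:
                return self.a1, a2, a3
        raise KeyError(
            f"no calibrated constants for NA={na}; available: "
            f"{sorted(self.a2a3)} (supply your own ModelConstants to use "
            "another aperture — values are not interpolated)")

    @property
    def supported_na(self) -> tuple[float, ...]:
        return tuple(sorted(self.a2a3))


@dataclass(frozen=True)
class ModelPrediction:
    """Reflectance prediction split into diffuse and semiballistic parts."""

    R0: float
    R_dif_component: float
    R_sb_component: float
    X: float
    below_validity_limit: bool = False


def semiballistic_ratio(psb: float, musp_d: float,
                        constants: ModelConstants | None = None,
                        na: float = 0.22) -> float:
    """Semiballistic-to-diffuse ratio ``X = a2 * (psb / (musp_d)^2)^a3``."""
    if psb <= 0:
        raise ValueError("psb must be > 0")
    if musp_d <= 0:
        raise ValueError("musp_d must be > 0")
    constants = constants or ModelConstants()
    _, a2, a3 = constants.for_na(na)
    return a2 * (psb / musp_d ** 2) ** a3


def predict_R0(model_or_psb: PhaseFunction | float, musp_d: float,
               probe: ProbeConfig,
               constants: ModelConstants | None = None) -> ModelPrediction:
    """Predict the absorption-free single-fiber reflectance.

    Parameters
    ----------
    model_or_psb : PhaseFunction or float
        Either a phase-function model (psb is derived from it) or a psb
        value directly (e.g. during spectral fitting).
    musp_d : float
        Product of reduced scattering coefficient and fiber diameter
        (dimensionless).  Values below 0.1 evaluate but carry a validity
        flag and emit a :class:`ValidityWarning`.
    probe : ProbeConfig
        Probe geometry; its NA selects the calibration constants.
    """
    if musp_d <= 0:
        raise ValueError("musp_d must be > 0")
    psb_val = (_psb_of_model(model_or_psb)
               if isinstance(model_or_psb, PhaseFunction)
               else float(model_or_psb))
    constants = constants or ModelConstants()
    a1, _, _ = constants.for_na(probe.na)

    x = semiballistic_ratio(psb_val, musp_d, constants, probe.na)
    r_dif = collection_efficiency(probe, a1) * diffuse_reflectance(musp_d, probe.A)
    below = musp_d < MUSP_D_VALIDITY_LIMIT
    if below:
        warnings.warn(
            f"musp_d={musp_d} is below the validity limit "
            f"{MUSP_D_VALIDITY_LIMIT}; prediction is unreliable",
            ValidityWarning, stacklevel=2)
    return ModelPrediction(
        R0=(1.0 + x) * r_dif,
        R_dif_component=r_dif,
        R_sb_component=x * r_dif,
        X=x,
        below_validity_limit=below,
    )


def kanick_R0(gamma: float, musp_d: float, probe: ProbeConfig) -> float:
    """Single-fiber reflectance of the gamma-based comparison model.

    .. math::

        R_0 = \\left(\\frac{NA}{n}\\right)^2
              \\left(1 + 0.632\\,\\gamma^2 e^{-2.308\\gamma^2 \\mu_s' d}\\right)
              \\frac{(\\mu_s' d)^{0.574\\gamma}}
                   {2.308\\,\\gamma^2 + (\\mu_s' d)^{0.574\\gamma}}.

    Vanishes as ``musp_d -> 0`` and saturates for large ``musp_d``.
    """
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    if musp_d <= 0:
        raise ValueError("musp_d must be > 0")
    eta = (probe.na / probe.n_sample) ** 2
    g2 = gamma * gamma
    sat = musp_d ** (0.574 * gamma)
    return eta * (1.0 + 0.632 * g2 * np.exp(-2.308 * g2 * musp_d)) * sat / (2.308 * g2 + sat)
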