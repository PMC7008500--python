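"""Scalar phase-function summaries for subdiffuse reflectance.

Single-fiber reflectance at source–detector separations below the transport
mean free path mixes diffuse photons with "semiballistic" photons that have
undergone exactly one backscattering event.  Several scalar summaries of the
phase function have been proposed to capture the semiballistic contribution:

* ``gamma = (1 - g2)/(1 - g1)`` and ``delta = (1 - g3)/(1 - g1)`` — moment
  ratios,
* ``sigma = sum_{i>=2} (-1/2)^(i-2) (1 - g_i)/(1 - g_1)`` — an alternating
  moment series,
* ``Rp(theta_b, theta_f) = p_b(theta_b) / (1 - p_f(theta_f))`` — a ratio of
  partial phase-function integrals over a backward and a forward cone,
* ``RpNA`` — ``Rp`` evaluated at the fiber acceptance angle in both
  directions,
* ``psb = p_b(1 deg) / (1 - p_f(23 deg))`` — the parameter used by the
  semiballistic reflectance model; its angles are fixed constants of the
  model (optimized once for an NA of 0.22), not probe-derived.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diffuse import ProbeConfig
from .phase_functions import MomentSet, PhaseFunction, PhaseFunctionGrid

__all__ = [
    "AnglePair",
    "SubdiffuseParameterSet",
    "PSB_ANGLES",
    "moment_parameters",
    "rp_parameter",
    "rp_na",
    "psb",
    "named_parameters",
    "parameter_table",
]

#: Backward and forward integration angles (degrees) defining psb.
PSB_ANGLES: tuple[float, float] = (1.0, 23.0)

_SIGMA_TOL = 1e-10


@dataclass(frozen=True)
class AnglePair:
    """Backward/forward integration angles in degrees, each in (0, 90]."""

    theta_b: float
    theta_f: float

    def __post_init__(self) -> None:
        for name, v in (("theta_b", self.theta_b), ("theta_f", self.theta_f)):
            if not 0.0 < v <= 90.0:
                raise ValueError(f"{name}={v} deg outside (0, 90]")


@dataclass(frozen=True)
class SubdiffuseParameterSet:
    """The scalar summaries gamma, delta, sigma, RpNA and psb for one model."""

    gamma: float
    delta: float
    sigma: float
    rpna: float
    psb: float


def moment_parameters(moments: MomentSet,
                      sigma_budget: int | None = None) -> tuple[float, float, float]:
    """Compute (gamma, delta, sigma) from a set of Legendre moments.

    The sigma series is summed until a term falls below 1e-10 in magnitude;
    because successive terms carry a factor of -1/2, the truncation error is
    bounded by the last term.  Raises if the supplied moments are exhausted
    before convergence, reporting the partial sum.
    """
    g1 = moments[1]
    if g1 >= 1.0 - 1e-12:
        raise ZeroDivisionError("g1 = 1: degenerate forward scattering, "
                                "gamma/delta/sigma undefined")
    if len(moments) < 3:
        raise ValueError("at least 3 moments required")
    gamma = (1.0 - moments[2]) / (1.0 - g1)
    delta = (1.0 - moments[3]) / (1.0 - g1)

    budget = len(moments) if sigma_budget is None else min(sigma_budget, len(moments))
    sigma = 0.0
    converged = False
    for i in range(2, budget + 1):
        term = (-0.5) ** (i - 2) * (1.0 - moments[i]) / (1.0 - g1)
        sigma += term
        if abs(term) < _SIGMA_TOL:
            converged = True
            break
    if not converged:
        # moments decay to 0, so the tail behaves like sum of (-1/2)^k / (1-g1);
        # if that bound is already below tolerance the sum is converged anyway.
        tail_bound = 0.5 ** (budget - 1) * 2.0 / (1.0 - g1)
        if tail_bound >= _SIGMA_TOL:
            raise ArithmeticError(
                f"sigma series not converged within {budget} moments; "
                f"partial sum = {sigma!r}"
            )
    return float(gamma), float(delta), float(sigma)


def rp_parameter(model: PhaseFunction, angles: AnglePair) -> float:
    """``Rp(theta_b, theta_f) = p_b(theta_b) / (1 - p_f(theta_f))``.

    ``p_b`` integrates the phase function over a cone of half-angle
    ``theta_b`` about the exact backward direction, ``p_f`` over ``theta_f``
    about the forward direction.
    """
    pb = model.partial_integral(np.deg2rad(angles.theta_b), "backward")
    pf = model.partial_integral(np.deg2rad(angles.theta_f), "forward")
    if pf >= 1.0 - 1e-15:
        raise ZeroDivisionError("forward partial integral reaches 1; Rp undefined")
    return pb / (1.0 - pf)


def rp_na(model: PhaseFunction, probe: ProbeConfig) -> float:
    """``RpNA``: Rp evaluated at the probe acceptance angle both ways."""
    acc_deg = np.rad2deg(probe.theta_acc)
    return rp_parameter(model, AnglePair(acc_deg, acc_deg))


def psb(model: PhaseFunction) -> float:
    """The semiballistic phase-function parameter ``p_b(1°)/(1 - p_f(23°))``."""
    return rp_parameter(model, AnglePair(*PSB_ANGLES))


def named_parameters(model: PhaseFunction, probe: ProbeConfig,
                     n_moments: int = 64) -> SubdiffuseParameterSet:
    """All scalar summaries for one phase function and probe geometry."""
    gamma, delta, sigma = moment_parameters(model.moments(n_moments))
    return SubdiffuseParameterSet(
        gamma=gamma,
        delta=delta,
        sigma=sigma,
        rpna=rp_na(model, probe),
        psb=psb(model),
    )


def parameter_table(grid: PhaseFunctionGrid,
                    probes: dict[float, ProbeConfig] | ProbeConfig,
                    n_moments: int = 64) -> pd.DataFrame:
    """Batch-compute the parameter summaries for an ensemble of models.

    ``probes`` may be a single :class:`ProbeConfig` or a mapping from NA to
    probe, in which case one ``rpna_NA`` column is emitted per NA.
    """
    if isinstance(probes, ProbeConfig):
        probes = {probes.na: probes}
    rows = []
    for i, model in enumerate(grid.models):
        mom = model.moments(n_moments)
        gamma, delta, sigma = moment_parameters(mom)
        row = {
            "model_id": i,
            "family": model.family,
            "provenance": grid.provenance[i],
            "g1": mom[1], "g2": mom[2], "g3": mom[3],
            "gamma": gamma, "delta": delta, "sigma": sigma,
            "psb": psb(model),
        }
        for na, probe in probes.items():
            row[f"rpna_{na:.2f}"] = rp_na(model, probe)
        rows.append(row)
    return pd.DataFrame(rows)
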