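"""Diffuse reflectance for an overlapping source/detector fiber.

The diffuse component of single-fiber reflectance is the Farrell pencil-beam
solution of the diffusion approximation (zero absorption), averaged over the
distribution of distances between two random points on the fiber face:

.. math::

    R_{dif}(\\mu_s' d) = \\frac{\\pi d^2}{4}
        \\int_0^d R_{\\mu_a=0}(\\rho, \\mu_s')\\, p(\\rho, d)\\, d\\rho ,

where :math:`R_{\\mu_a=0}` is the pencil-beam diffuse reflectance with the
extrapolated-boundary condition (internal-reflection parameter ``A``) and
``p(rho, d)`` is the classic disk chord-length density.  ``R_dif`` depends on
``mu_s'`` and ``d`` only through their product and tends to 1 as
``mu_s' d -> infinity`` (every photon eventually re-crosses the fiber face
when there is no absorption).

Detection further requires arrival within the fiber acceptance angle
``theta_acc = arcsin(NA / n_sample)``; for a Lambertian angular profile the
collection efficiency is ``sin^2(theta_acc)``, scaled by the calibration
constant ``a1`` to absorb the true (non-Lambertian) profile.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.integrate import quad
from scipy.interpolate import CubicSpline

__all__ = [
    "ProbeConfig",
    "boundary_parameter_A",
    "pencil_beam_reflectance",
    "chord_pdf",
    "diffuse_reflectance",
    "collection_efficiency",
    "tabulate_diffuse_reflectance",
]

#: Boundary parameter for the tissue(1.35)/fiber(1.45) interface.
A_DEFAULT = 1.027


def _fresnel_unpolarized(cos_i: float, n_rel: float) -> float:
    """Unpolarized Fresnel reflectance; ``n_rel = n_transmitted/n_incident``."""
    cos_i = min(max(cos_i, 0.0), 1.0)
    sin_t = math.sqrt(max(1.0 - cos_i * cos_i, 0.0)) / n_rel
    if sin_t >= 1.0:
        return 1.0
    cos_t = math.sqrt(1.0 - sin_t * sin_t)
    rs = ((cos_i - n_rel * cos_t) / (cos_i + n_rel * cos_t)) ** 2
    rp = ((n_rel * cos_i - cos_t) / (n_rel * cos_i + cos_t)) ** 2
    return 0.5 * (rs + rp)


@lru_cache(maxsize=64)
def boundary_parameter_A(n_sample: float, n_contact: float) -> float:
    """Diffusion-theory internal-reflection parameter for an index mismatch.

    Uses the effective reflection coefficient obtained from the Fresnel
    hemispheric integrals of the fluence-rate and flux moments,

    .. math::

        R_\\phi = \\int_0^{\\pi/2} 2 \\sin\\theta \\cos\\theta R_F(\\theta)
                   d\\theta, \\quad
        R_j = \\int_0^{\\pi/2} 3 \\sin\\theta \\cos^2\\theta R_F(\\theta)
                   d\\theta,

    ``R_eff = (R_phi + R_j) / (2 - R_phi + R_j)`` and
    ``A = (1 + R_eff) / (1 - R_eff)``.  Matched indices give exactly 1.
    """
    if n_sample <= 0 or n_contact <= 0:
        raise ValueError("refractive indices must be positive")
    n_rel = n_contact / n_sample
    if abs(n_rel - 1.0) < 1e-12:
        return 1.0
    r_phi = quad(lambda t: 2.0 * math.sin(t) * math.cos(t)
                 * _fresnel_unpolarized(math.cos(t), n_rel), 0.0, math.pi / 2)[0]
    r_j = quad(lambda t: 3.0 * math.sin(t) * math.cos(t) ** 2
               * _fresnel_unpolarized(math.cos(t), n_rel), 0.0, math.pi / 2)[0]
    r_eff = (r_phi + r_j) / (2.0 - r_phi + r_j)
    return (1.0 + r_eff) / (1.0 - r_eff)


@dataclass(frozen=True)
class ProbeConfig:
    """Fiber-probe and sample geometry.

    Parameters
    ----------
    d : float
        Fiber (core) diameter in cm.
    na : float
        Numerical aperture; must satisfy ``0 < NA < n_sample``.
    n_sample, n_fiber, n_external : float
        Refractive indices of the sample, the fiber face, and the medium
        above the sample outside the fiber.
    A : float, optional
        Internal-reflection boundary parameter.  Defaults to the value
        computed from the sample/fiber mismatch (the interface the diffuse
        model sees).
    """

    d: float
    na: float = 0.22
    n_sample: float = 1.35
    n_fiber: float = 1.45
    n_external: float = 1.00
    A: float = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.d <= 0:
            raise ValueError(f"fiber diameter d={self.d} must be > 0")
        for name in ("n_sample", "n_fiber", "n_external"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 < self.na < self.n_sample:
            raise ValueError(
                f"NA={self.na} must satisfy 0 < NA < n_sample={self.n_sample}")
        if self.A is None:
            object.__setattr__(
                self, "A", boundary_parameter_A(self.n_sample, self.n_fiber))
        elif self.A <= 0:
            raise ValueError(f"A={self.A} must be > 0")

    @property
    def theta_acc(self) -> float:
        """Acceptance angle inside the sample, ``arcsin(NA/n_sample)`` (rad)."""
        return math.asin(self.na / self.n_sample)

    def with_diameter(self, d: float) -> "ProbeConfig":
        return ProbeConfig(d=d, na=self.na, n_sample=self.n_sample,
                           n_fiber=self.n_fiber, n_external=self.n_external,
                           A=self.A)


def pencil_beam_reflectance(rho, musp: float, A: float = A_DEFAULT):
    """Zero-absorption pencil-beam diffuse reflectance density (1/cm^2).

    Image-source solution with the source at depth ``1/musp`` and its mirror
    at the extrapolated boundary:

    .. math::

        R(\\rho) = \\frac{1}{4\\pi}\\left\\{
          \\frac{\\mu_s'^2}{[1 + (\\mu_s'\\rho)^2]^{3/2}}
          + \\frac{(1 + 4A/3)\\,\\mu_s'^2}
                 {[(1 + 4A/3)^2 + (\\mu_s'\\rho)^2]^{3/2}} \\right\\}.

    Finite at ``rho = 0``, strictly decreasing, asymptotically ``rho**-3``.
    """
    if musp <= 0:
        raise ValueError("musp must be > 0")
    rho = np.asarray(rho, dtype=float)
    if np.any(rho < 0):
        raise ValueError("rho must be >= 0")
    u2 = (musp * rho) ** 2
    zb = 1.0 + 4.0 * A / 3.0
    return (musp ** 2 / (4.0 * np.pi)) * (
        (1.0 + u2) ** -1.5 + zb * (zb * zb + u2) ** -1.5
    )


def chord_pdf(rho, d: float):
    """Density of the distance between two uniform random points on a disk.

    For a disk of diameter ``d`` (1/cm units):

    .. math::

        p(\\rho, d) = \\frac{16\\rho}{\\pi d^2}\\left[
            \\cos^{-1}\\frac{\\rho}{d}
            - \\frac{\\rho}{d}\\sqrt{1 - (\\rho/d)^2}\\right].

    Vanishes at both endpoints, integrates to 1, mean ``64 d / (45 pi)``.
    """
    if d <= 0:
        raise ValueError("d must be > 0")
    rho = np.asarray(rho, dtype=float)
    if np.any(rho < -1e-12) or np.any(rho > d * (1 + 1e-12)):
        raise ValueError("rho must lie in [0, d]")
    t = np.clip(rho / d, 0.0, 1.0)
    return (16.0 * rho / (np.pi * d * d)) * (np.arccos(t) - t * np.sqrt(1.0 - t * t))


def diffuse_reflectance(musp_d, A: float = A_DEFAULT):
    """Diffuse reflected fraction arriving anywhere on the fiber face.

    Depends on scattering and geometry only through ``musp_d = mu_s' * d``;
    scales as ``(musp_d)**2`` for small arguments and tends to 1 for large
    ones.  Evaluated by adaptive quadrature on the unit-diameter form.
    """
    scalar = np.isscalar(musp_d)
    vals = np.atleast_1d(np.asarray(musp_d, dtype=float))
    if np.any(vals <= 0):
        raise ValueError("musp_d must be > 0")
    out = np.empty_like(vals)
    for i, x in enumerate(vals):
        # unit diameter: rho in [0, 1], musp = musp_d
        f = lambda r: pencil_beam_reflectance(r, x, A) * chord_pdf(r, 1.0)
        val, err = quad(f, 0.0, 1.0, epsrel=1e-8, epsabs=0.0, limit=200)
        if not np.isfinite(val) or (val > 0 and err / val > 1e-6):
            raise ArithmeticError(
                f"diffuse reflectance quadrature failed at musp_d={x}: "
                f"value={val}, abserr={err}")
        out[i] = (np.pi / 4.0) * val
    return float(out[0]) if scalar else out


@lru_cache(maxsize=8)
def _rdif_spline(A_key: float) -> CubicSpline:
    x = np.logspace(-3, 4, 600)
    y = diffuse_reflectance(x, A_key)
    return CubicSpline(np.log(x), np.log(y))


def diffuse_reflectance_fast(musp_d, A: float = A_DEFAULT):
    """Spline-accelerated ``diffuse_reflectance`` (relative error < 1e-7).

    Used inside iterative fits; falls back to exact quadrature outside the
    tabulated range 1e-3..1e4.
    """
    vals = np.atleast_1d(np.asarray(musp_d, dtype=float))
    if np.any(vals <= 0):
        raise ValueError("musp_d must be > 0")
    spl = _rdif_spline(round(float(A), 12))
    out = np.exp(spl(np.log(vals)))
    outside = (vals < 1e-3) | (vals > 1e4)
    if np.any(outside):
        out[outside] = np.atleast_1d(diffuse_reflectance(vals[outside], A))
    return float(out[0]) if np.isscalar(musp_d) else out


def collection_efficiency(probe: ProbeConfig, a1: float = 1.0) -> float:
    """Fiber collection efficiency ``eta_c = a1 * sin^2(theta_acc)``.

    ``a1 = 1`` gives the Lambertian-profile efficiency ``(NA/n_sample)^2``.
    """
    if a1 <= 0:
        raise ValueError("a1 must be > 0")
    return a1 * math.sin(probe.theta_acc) ** 2


def tabulate_diffuse_reflectance(musp_d_min: float = 1e-2,
                                 musp_d_max: float = 1e4,
                                 n: int = 200,
                                 A: float = A_DEFAULT):
    """Log-spaced table of ``R_dif`` versus ``mu_s' d`` (for plotting/export)."""
    import pandas as pd

    x = np.logspace(np.log10(musp_d_min), np.log10(musp_d_max), n)
    return pd.DataFrame({"musp_d": x, "R_dif": diffuse_reflectance(x, A)})
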