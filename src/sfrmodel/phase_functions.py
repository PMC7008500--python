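"""Scattering phase functions for tissue optics.

A phase function :math:`p(\\theta)` is the probability density of the polar
scattering angle, normalized over the unit sphere:

.. math:: 2\\pi \\int_0^{\\pi} p(\\theta) \\sin\\theta \\, d\\theta = 1.

Four families commonly used to describe biological tissue are provided:

* :class:`HenyeyGreenstein` (HG) — single-parameter kernel with asymmetry
  ``g``; Legendre moments are ``g**n``.
* :class:`ModifiedHenyeyGreenstein` (MHG) — convex mixture of an HG kernel
  and an isotropic-dipole ``cos^2`` term, ``p = a*p_HG(g) + (1-a)*(3/4pi)cos^2``.
* :class:`TwoTermHenyeyGreenstein` (TTHG) — mixture of a forward HG lobe
  (``gf > 0``) and a backward HG lobe (``gb < 0``).
* :class:`GegenbauerKernel` (Reynolds–McCormick, RMC) — generalized HG with
  exponent ``alpha``; reduces to HG at ``alpha = 1/2``.

All families expose evaluation, Legendre moments, closed-form partial
(forward/backward cone) integrals, and inverse-CDF sampling.  The module also
builds the parameter-grid ensemble of biologically plausible phase functions
(``g1 >= 0.5`` and ``g2 < 0.9``) used to derive and validate the subdiffuse
reflectance model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from numpy.polynomial.legendre import leggauss, legvander

__all__ = [
    "PhaseFunction",
    "HenyeyGreenstein",
    "ModifiedHenyeyGreenstein",
    "TwoTermHenyeyGreenstein",
    "GegenbauerKernel",
    "MomentSet",
    "PhaseFunctionGrid",
    "build_tissue_grid",
]

_QUAD_ORDER = 2048
_GL_X, _GL_W = leggauss(_QUAD_ORDER)


def _check_range(name: str, value: float, lo: float, hi: float,
                 lo_open: bool = False, hi_open: bool = False) -> None:
    bad = (value <= lo if lo_open else value < lo) or \
          (value >= hi if hi_open else value > hi)
    if bad:
        lo_b = "(" if lo_open else "["
        hi_b = ")" if hi_open else "]"
        raise ValueError(
            f"parameter {name}={value} outside domain {lo_b}{lo}, {hi}{hi_b}"
        )


def _hg_pdf_mu(mu: np.ndarray, g: float) -> np.ndarray:
    """HG density per steradian as a function of mu = cos(theta)."""
    if abs(g) < 1e-12:
        return np.full_like(np.asarray(mu, dtype=float), 1.0 / (4.0 * np.pi))
    return (1.0 - g * g) / (4.0 * np.pi * (1.0 + g * g - 2.0 * g * mu) ** 1.5)


def _hg_cone_integral(mu_lo: float, mu_hi: float, g: float) -> float:
    """2*pi * integral of the HG density over mu in [mu_lo, mu_hi]."""
    if abs(g) < 1e-12:
        return 0.5 * (mu_hi - mu_lo)
    f = lambda mu: (1.0 - g * g) / (2.0 * g * np.sqrt(1.0 + g * g - 2.0 * g * mu))
    return f(mu_hi) - f(mu_lo)


@dataclass(frozen=True)
class MomentSet:
    """Ordered Legendre moments ``g1..gN`` of a phase function.

    ``g0 = 1`` is implicit (normalization).  ``|gn| <= 1`` for all n.
    """

    g: np.ndarray

    def __post_init__(self) -> None:
        g = np.asarray(self.g, dtype=float)
        object.__setattr__(self, "g", g)
        if g.ndim != 1 or g.size < 1:
            raise ValueError("MomentSet requires a 1-D sequence of moments g1..gN")
        if np.any(np.abs(g) > 1.0 + 1e-9):
            raise ValueError("Legendre moments must satisfy |gn| <= 1")

    def __getitem__(self, n: int) -> float:
        if n == 0:
            return 1.0
        return float(self.g[n - 1])

    def __len__(self) -> int:
        return self.g.size

    @property
    def g1(self) -> float:
        return self[1]

    @property
    def g2(self) -> float:
        return self[2]

    @property
    def g3(self) -> float:
        return self[3]


class PhaseFunction:
    """Base class: a normalized scattering-angle density on [0, pi]."""

    family: str = "base"

    # -- evaluation -------------------------------------------------------
    def pdf_mu(self, mu):
        """Density per steradian as a function of mu = cos(theta)."""
        raise NotImplementedError

    def pdf(self, theta):
        """Density per steradian at polar angle ``theta`` (radians, in [0, pi])."""
        theta = np.asarray(theta, dtype=float)
        if np.any(theta < -1e-12) or np.any(theta > np.pi + 1e-12):
            raise ValueError("theta must lie in [0, pi]")
        return self.pdf_mu(np.cos(theta))

    # -- moments ----------------------------------------------------------
    def moments(self, n_max: int) -> MomentSet:
        """Legendre moments ``g1..g_{n_max}``.

        The generic implementation uses fixed-order Gauss–Legendre quadrature
        in ``mu = cos(theta)``; subclasses with closed forms override it.
        """
        if n_max < 1:
            raise ValueError("n_max must be >= 1")
        p = self.pdf_mu(_GL_X)
        # legvander gives P_0..P_n at the nodes; integrate 2*pi*p*P_n dmu
        pn = legvander(_GL_X, n_max)
        g = 2.0 * np.pi * (pn.T * (_GL_W * p)).sum(axis=1)
        g0 = g[0]
        if abs(g0 - 1.0) > 1e-6:
            raise ArithmeticError(
                f"moment quadrature failed to converge: g0 = {g0!r} (should be 1)"
            )
        return MomentSet(np.clip(g[1:], -1.0, 1.0))

    @property
    def g1(self) -> float:
        return self.moments(1)[1]

    @property
    def g2(self) -> float:
        return self.moments(2)[2]

    # -- partial (cone) integrals -----------------------------------------
    def cone_integral_mu(self, mu_lo: float, mu_hi: float) -> float:
        """2*pi * integral of ``pdf_mu`` over ``mu`` in [mu_lo, mu_hi].

        Generic quadrature fallback; families override with closed forms.
        """
        x = 0.5 * (mu_hi - mu_lo) * _GL_X + 0.5 * (mu_hi + mu_lo)
        w = 0.5 * (mu_hi - mu_lo) * _GL_W
        return float(2.0 * np.pi * np.sum(w * self.pdf_mu(x)))

    def partial_integral(self, theta_lim: float, direction: str) -> float:
        """Probability of scattering within ``theta_lim`` of forward/backward.

        ``forward`` returns ``2*pi*int_0^theta_lim p sin(theta) dtheta``;
        ``backward`` integrates over ``[pi - theta_lim, pi]``.  ``theta_lim``
        is in radians and must lie in (0, pi/2].
        """
        if not 0.0 < theta_lim <= np.pi / 2 + 1e-12:
            raise ValueError("theta_lim must lie in (0, pi/2]")
        c = np.cos(theta_lim)
        if direction == "forward":
            val = self.cone_integral_mu(c, 1.0)
        elif direction == "backward":
            val = self.cone_integral_mu(-1.0, -c)
        else:
            raise ValueError("direction must be 'forward' or 'backward'")
        return float(min(max(val, 0.0), 1.0))

    # -- sampling ---------------------------------------------------------
    _TABLE_SIZE = 2 ** 14

    def _inverse_cdf_table(self) -> tuple[np.ndarray, np.ndarray]:
        """(cdf, mu) table for inverse-CDF sampling of mu = cos(theta).

        Tabulated on a uniform mu grid (Zijp–ten Bosch style); the CDF is the
        cumulative trapezoid of ``2*pi*pdf_mu``, rescaled to end exactly at 1.
        """
        mu = np.linspace(-1.0, 1.0, self._TABLE_SIZE + 1)
        dens = 2.0 * np.pi * self.pdf_mu(mu)
        cdf = np.concatenate(
            [[0.0], np.cumsum(0.5 * (dens[1:] + dens[:-1]) * np.diff(mu))]
        )
        cdf /= cdf[-1]
        return cdf, mu

    def sample_mu(self, n: int, seed: int | np.random.Generator) -> np.ndarray:
        """Draw ``n`` scattering-angle cosines, reproducibly under ``seed``."""
        if n < 1:
            raise ValueError("n must be >= 1")
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        cdf, mu = self._inverse_cdf_table()
        return np.interp(rng.random(n), cdf, mu)

    def sample_angles(self, n: int, seed: int | np.random.Generator) -> np.ndarray:
        """Draw ``n`` polar scattering angles (radians, in [0, pi])."""
        return np.arccos(np.clip(self.sample_mu(n, seed), -1.0, 1.0))

    # -- misc -------------------------------------------------------------
    @property
    def params(self) -> dict[str, float]:
        return {k: v for k, v in self.__dict__.items()}

    def label(self) -> str:
        pars = ", ".join(f"{k}={v:.4g}" for k, v in self.params.items())
        return f"{self.family}({pars})"


@dataclass(frozen=True)
class HenyeyGreenstein(PhaseFunction):
    """Henyey–Greenstein kernel with asymmetry ``g`` in (-1, 1)."""

    g: float
    family = "HG"

    def __post_init__(self) -> None:
        _check_range("gHG", self.g, -1.0, 1.0, lo_open=True, hi_open=True)

    def pdf_mu(self, mu):
        return _hg_pdf_mu(np.asarray(mu, dtype=float), self.g)

    def moments(self, n_max: int) -> MomentSet:
        if n_max < 1:
            raise ValueError("n_max must be >= 1")
        return MomentSet(self.g ** np.arange(1, n_max + 1))

    def cone_integral_mu(self, mu_lo: float, mu_hi: float) -> float:
        return _hg_cone_integral(mu_lo, mu_hi, self.g)


@dataclass(frozen=True)
class ModifiedHenyeyGreenstein(PhaseFunction):
    """MHG: ``p = alpha*p_HG(g) + (1 - alpha)*(3/4pi)*cos^2(theta)``.

    The second component is the Rayleigh-like ``cos^2`` term; its only
    nonvanishing moment beyond g0 is ``g2 = 2/5``.
    """

    g: float
    alpha: float
    family = "MHG"

    def __post_init__(self) -> None:
        _check_range("gHG", self.g, -1.0, 1.0, lo_open=True, hi_open=True)
        _check_range("alpha", self.alpha, 0.0, 1.0)

    def pdf_mu(self, mu):
        mu = np.asarray(mu, dtype=float)
        return (self.alpha * _hg_pdf_mu(mu, self.g)
                + (1.0 - self.alpha) * (3.0 / (4.0 * np.pi)) * mu ** 2)

    def moments(self, n_max: int) -> MomentSet:
        if n_max < 1:
            raise ValueError("n_max must be >= 1")
        g = self.alpha * self.g ** np.arange(1, n_max + 1)
        if n_max >= 2:
            g[1] += (1.0 - self.alpha) * 0.4
        return MomentSet(g)

    def cone_integral_mu(self, mu_lo: float, mu_hi: float) -> float:
        hg = _hg_cone_integral(mu_lo, mu_hi, self.g)
        iso = 0.5 * (mu_hi ** 3 - mu_lo ** 3)  # 2*pi*(3/4pi)*int mu^2 dmu
        return self.alpha * hg + (1.0 - self.alpha) * iso


@dataclass(frozen=True)
class TwoTermHenyeyGreenstein(PhaseFunction):
    """TTHG: ``p = alpha*p_HG(gf) + (1 - alpha)*p_HG(gb)``, gf > 0 > gb."""

    alpha: float
    gf: float
    gb: float
    family = "TTHG"

    def __post_init__(self) -> None:
        _check_range("alpha", self.alpha, 0.0, 1.0)
        _check_range("gf", self.gf, 0.0, 1.0, lo_open=True, hi_open=True)
        _check_range("gb", self.gb, -1.0, 0.0, lo_open=True, hi_open=True)

    def pdf_mu(self, mu):
        mu = np.asarray(mu, dtype=float)
        return (self.alpha * _hg_pdf_mu(mu, self.gf)
                + (1.0 - self.alpha) * _hg_pdf_mu(mu, self.gb))

    def moments(self, n_max: int) -> MomentSet:
        if n_max < 1:
            raise ValueError("n_max must be >= 1")
        n = np.arange(1, n_max + 1)
        return MomentSet(self.alpha * self.gf ** n + (1.0 - self.alpha) * self.gb ** n)

    def cone_integral_mu(self, mu_lo: float, mu_hi: float) -> float:
        return (self.alpha * _hg_cone_integral(mu_lo, mu_hi, self.gf)
                + (1.0 - self.alpha) * _hg_cone_integral(mu_lo, mu_hi, self.gb))


@dataclass(frozen=True)
class GegenbauerKernel(PhaseFunction):
    """Reynolds–McCormick (Gegenbauer-kernel) phase function.

    .. math::

        p(\\theta) = K (1 + g^2 - 2 g \\cos\\theta)^{-(\\alpha + 1)},
        \\qquad
        K = \\frac{\\alpha g (1 - g^2)^{2\\alpha}}
                 {\\pi [(1+g)^{2\\alpha} - (1-g)^{2\\alpha}]}

    with ``alpha > 0`` and ``g`` in (0, 1).  ``alpha = 1/2`` recovers HG.
    """

    alpha: float
    g: float
    family = "RMC"

    def __post_init__(self) -> None:
        if self.alpha <= 0.0:
            raise ValueError(f"parameter alpha={self.alpha} must be > 0")
        _check_range("gR", self.g, 0.0, 1.0, lo_open=True, hi_open=True)

    def _norm(self) -> float:
        a, g = self.alpha, self.g
        return (a * g * (1.0 - g * g) ** (2.0 * a)
                / (np.pi * ((1.0 + g) ** (2.0 * a) - (1.0 - g) ** (2.0 * a))))

    def pdf_mu(self, mu):
        mu = np.asarray(mu, dtype=float)
        a, g = self.alpha, self.g
        return self._norm() * (1.0 + g * g - 2.0 * g * mu) ** (-(a + 1.0))

    def cone_integral_mu(self, mu_lo: float, mu_hi: float) -> float:
        # antiderivative of (1+g^2-2g mu)^-(a+1) is (1+g^2-2g mu)^-a / (2 g a)
        a, g = self.alpha, self.g
        K = self._norm()
        f = lambda mu: (1.0 + g * g - 2.0 * g * mu) ** (-a) / (2.0 * g * a)
        return float(2.0 * np.pi * K * (f(mu_hi) - f(mu_lo)))


@dataclass(frozen=True)
class PhaseFunctionGrid:
    """Ensemble of phase functions surviving the biological-plausibility filter."""

    models: tuple[PhaseFunction, ...]
    provenance: tuple[str, ...]
    moments: tuple[MomentSet, ...]

    def __len__(self) -> int:
        return len(self.models)

    def counts_by_family(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for m in self.models:
            out[m.family] = out.get(m.family, 0) + 1
        return out

    def to_frame(self) -> pd.DataFrame:
        """Tabulate family, parameters and the first three moments."""
        rows = []
        for m, prov, mom in zip(self.models, self.provenance, self.moments):
            row = {"family": m.family, "provenance": prov}
            for k, v in m.params.items():
                row[f"param_{k}"] = v
            row.update(g1=mom[1], g2=mom[2], g3=mom[3])
            rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _lin(lo: float, hi: float, n: int) -> np.ndarray:
    """n equally spaced values inclusive of both endpoints."""
    return np.linspace(lo, hi, n)


# Parameter grids of the ensemble (family: list of (provenance, model) rows).
# "N linear steps" is read as N equally spaced values including endpoints;
# this reading is validated by the MHG and RMC survivor counts (15 and 46).
def _grid_candidates() -> Iterable[tuple[str, PhaseFunction]]:
    for g in _lin(0.01, 0.95, 10):
        for a in _lin(0.01, 0.99, 10):
            yield f"MHG gHG={g:.3f} alpha={a:.3f}", ModifiedHenyeyGreenstein(g=g, alpha=a)
    tthg_alphas = np.concatenate([_lin(0.5, 0.9, 3), _lin(0.91, 0.99, 5)])
    for a in tthg_alphas:
        for gf in _lin(0.05, 0.95, 10):
            for gb in _lin(-0.95, -0.05, 5):
                yield (f"TTHG alpha={a:.3f} gf={gf:.3f} gb={gb:.3f}",
                       TwoTermHenyeyGreenstein(alpha=a, gf=gf, gb=gb))
    for a in _lin(0.01, 2.5, 10):
        for gr in _lin(0.01, 0.95 - 0.2 * a, 10):
            yield f"RMC alpha={a:.3f} gR={gr:.3f}", GegenbauerKernel(alpha=a, g=gr)


def build_tissue_grid(n_moments: int = 3) -> PhaseFunctionGrid:
    """Build the phase-function ensemble and filter to plausible tissue shapes.

    All MHG, TTHG and RMC parameter combinations of the standard grids are
    generated, and models are kept only if ``g1 >= 0.5`` and ``g2 < 0.9``
    (excluding weakly forward or unrealistically anisotropic shapes).  The
    result is deterministic.
    """
    models, prov, moms = [], [], []
    n_req = max(n_moments, 2)
    for label, model in _grid_candidates():
        mom = model.moments(n_req)
        if mom[1] >= 0.5 and mom[2] < 0.9:
            models.append(model)
            prov.append(label)
            moms.append(mom)
    return PhaseFunctionGrid(tuple(models), tuple(prov), tuple(moms))


def export_tabulation(model: PhaseFunction, path, n_points: int = 1801) -> None:
    """Write a two-column CSV (theta in degrees, p per steradian)."""
    theta_deg = np.linspace(0.0, 180.0, n_points)
    p = model.pdf(np.deg2rad(theta_deg))
    pd.DataFrame({"theta_deg": theta_deg, "p_per_sr": p}).to_csv(path, index=False)
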