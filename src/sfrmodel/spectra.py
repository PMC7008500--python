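"""Multidiameter single-fiber reflectance spectra: synthesis and inversion.

A single-fiber reflectance spectrum at one diameter has as many data points
as wavelengths but needs one free ``psb`` per wavelength plus two scattering
parameters — an underdetermined fit.  Measuring the same medium with two
fiber diameters doubles the data (``2*n_lambda`` points) while the parameter
count stays ``2 + n_lambda``, making the joint inversion well-posed.

The reduced scattering spectrum is modelled as a power law

.. math:: \\mu_s'(\\lambda) = a (\\lambda / \\lambda_0)^{-b}

with amplitude ``a`` (1/cm at the reference wavelength), slope ``b``, and
``psb`` fitted freely per wavelength (positivity-bounded, no smoothness
prior).  :class:`MDSFRModel` is the statsmodels-style entry point: build it
from a :class:`SpectrumSet` (or a tidy DataFrame / CSV), call :meth:`fit`,
inspect the returned :class:`MDSFRResults` (parameters, standard errors,
residuals, ``summary()``).

This module is also the package's synthetic-data generator:
:func:`synthesize_spectra` produces the reference two-diameter spectra
(400–900 nm in 5-nm steps, 300- and 600-micron fibers by default) from the
forward model, optionally with multiplicative Gaussian noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.sparse import lil_matrix

from .diffuse import ProbeConfig, collection_efficiency, diffuse_reflectance_fast
from .forward import MUSP_D_VALIDITY_LIMIT, ModelConstants, ValidityWarning

__all__ = [
    "ScatteringPowerLaw",
    "SpectrumSet",
    "synthesize_spectra",
    "default_psb_curve",
    "MDSFRModel",
    "MDSFRResults",
    "DEFAULT_WAVELENGTHS",
    "DEFAULT_DIAMETERS_UM",
]

DEFAULT_WAVELENGTHS = np.arange(400.0, 900.0 + 2.5, 5.0)  # nm
DEFAULT_DIAMETERS_UM = (300.0, 600.0)
DEFAULT_LAMBDA0 = 600.0  # nm


@dataclass(frozen=True)
class ScatteringPowerLaw:
    """``mu_s'(lambda) = a * (lambda/lambda0)**-b`` (a in 1/cm, lambda in nm)."""

    a: float
    b: float
    lambda0: float = DEFAULT_LAMBDA0

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("scattering amplitude a must be > 0")
        if self.lambda0 <= 0:
            raise ValueError("reference wavelength lambda0 must be > 0")

    def musp(self, wavelengths_nm):
        return self.a * (np.asarray(wavelengths_nm, float) / self.lambda0) ** (-self.b)


@dataclass(frozen=True)
class SpectrumSet:
    """Reflectance spectra of one medium at several fiber diameters.

    ``reflectance`` maps fiber diameter in microns to an R0 array on the
    shared wavelength grid.  ``probe`` carries NA and indices; its own
    diameter is ignored (each spectrum sets its own).
    """

    wavelengths: np.ndarray
    reflectance: dict[float, np.ndarray]
    probe: ProbeConfig

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        refl = {float(d): np.asarray(r, dtype=float)
                for d, r in self.reflectance.items()}
        object.__setattr__(self, "reflectance", refl)
        for d, r in refl.items():
            if r.shape != wl.shape:
                raise ValueError(
                    f"spectrum for d={d} um not on the shared wavelength grid")
            if np.any(r <= 0):
                raise ValueError(f"reflectance must be positive (d={d} um)")

    @property
    def diameters_um(self) -> tuple[float, ...]:
        return tuple(sorted(self.reflectance))

    @property
    def n_wavelengths(self) -> int:
        return self.wavelengths.size

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for d in self.diameters_um:
            rows.append(pd.DataFrame({
                "wavelength_nm": self.wavelengths,
                "reflectance": self.reflectance[d],
                "fiber_diameter_um": d,
            }))
        return pd.concat(rows, ignore_index=True)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, probe: ProbeConfig) -> "SpectrumSet":
        req = {"wavelength_nm", "reflectance", "fiber_diameter_um"}
        if not req.issubset(frame.columns):
            raise ValueError(f"spectrum table must have columns {sorted(req)}")
        wl = None
        refl = {}
        for d, sub in frame.groupby("fiber_diameter_um"):
            sub = sub.sort_values("wavelength_nm")
            w = sub.wavelength_nm.to_numpy(dtype=float)
            if wl is None:
                wl = w
            elif not np.array_equal(wl, w):
                raise ValueError("wavelength grids differ between diameters")
            refl[float(d)] = sub.reflectance.to_numpy(dtype=float)
        return cls(wavelengths=wl, reflectance=refl, probe=probe)

    @classmethod
    def from_csv(cls, path, probe: ProbeConfig) -> "SpectrumSet":
        return cls.from_frame(pd.read_csv(path), probe)


def default_psb_curve(wavelengths_nm) -> np.ndarray:
    """Smooth synthetic-phantom psb spectrum, rising 1e-4 -> 1e-3 over the band.

    Log-linear in wavelength between 400 and 900 nm; a stand-in for a real
    medium's unknown psb dispersion (synthetic by construction).
    """
    wl = np.asarray(wavelengths_nm, dtype=float)
    t = (wl - 400.0) / 500.0
    return 10.0 ** (-4.0 + t)


def _forward_r0(psb, musp_d, probe, a1, a2, a3):
    x = a2 * (psb / musp_d ** 2) ** a3
    return (1.0 + x) * collection_efficiency(probe, a1) \
        * diffuse_reflectance_fast(musp_d, probe.A)


def synthesize_spectra(power_law: ScatteringPowerLaw,
                       psb_curve,
                       diameters_um: tuple[float, float] = DEFAULT_DIAMETERS_UM,
                       probe: ProbeConfig | None = None,
                       wavelengths_nm=DEFAULT_WAVELENGTHS,
                       noise_fraction: float = 0.0,
                       seed: int = 0,
                       constants: ModelConstants | None = None) -> SpectrumSet:
    """Generate a two-diameter reflectance spectrum set from the forward model.

    ``psb_curve`` is either a callable wavelength -> psb or an array on the
    wavelength grid.  Multiplicative Gaussian noise of relative magnitude
    ``noise_fraction`` is applied per point (seeded).  Wavelengths at which
    ``mu_s' d`` falls below the validity limit are flagged with a warning
    listing them.
    """
    probe = probe or ProbeConfig(d=1e-2)
    constants = constants or ModelConstants()
    a1, a2, a3 = constants.for_na(probe.na)
    wl = np.asarray(wavelengths_nm, dtype=float)
    psb = np.asarray(psb_curve(wl) if callable(psb_curve) else psb_curve,
                     dtype=float)
    if psb.shape != wl.shape or np.any(psb <= 0):
        raise ValueError("psb curve must be positive on the wavelength grid")
    musp = power_law.musp(wl)
    rng = np.random.default_rng(seed)
    refl = {}
    for d_um in diameters_um:
        d_cm = d_um * 1e-4
        musp_d = musp * d_cm
        bad = wl[musp_d < MUSP_D_VALIDITY_LIMIT]
        if bad.size:
            warnings.warn(
                f"mu_s'd below {MUSP_D_VALIDITY_LIMIT} for d={d_um} um at "
                f"wavelengths {bad.tolist()} nm", ValidityWarning, stacklevel=2)
        r0 = _forward_r0(psb, musp_d, probe, a1, a2, a3)
        if noise_fraction > 0:
            r0 = r0 * (1.0 + noise_fraction * rng.standard_normal(r0.size))
        refl[float(d_um)] = r0
    return SpectrumSet(wavelengths=wl, reflectance=refl, probe=probe)


class MDSFRModel:
    """Joint two-diameter spectral inversion for ``(a, b, psb(lambda))``.

    Parameters
    ----------
    spectra : SpectrumSet
        Exactly two fiber diameters on a shared wavelength grid.
    lambda0 : float
        Reference wavelength of the scattering power law (nm).
    constants : ModelConstants, optional
        Calibration constants; the probe's NA selects ``(a1, a2, a3)``.

    Notes
    -----
    The fit is trust-region nonlinear least squares on relative residuals
    ``R_model/R_meas - 1`` for all ``2*n_lambda`` points, over the
    ``2 + n_lambda`` parameters ``(a, b, psb_1..psb_n)``.  The Jacobian
    sparsity (each ``psb_i`` touches only its two wavelength points) is
    exploited.  A single-diameter input raises: the system would have more
    parameters than data points.
    """

    def __init__(self, spectra: SpectrumSet, lambda0: float = DEFAULT_LAMBDA0,
                 constants: ModelConstants | None = None):
        if len(spectra.diameters_um) < 2:
            raise ValueError(
                "underdetermined inversion: one diameter gives n_lambda data "
                "points but 2 + n_lambda parameters; measure a second fiber "
                "diameter")
        if len(spectra.diameters_um) != 2:
            raise ValueError("exactly two fiber diameters are supported")
        if spectra.n_wavelengths < 3:
            raise ValueError("at least 3 wavelengths required")
        self.spectra = spectra
        self.lambda0 = float(lambda0)
        self.constants = constants or ModelConstants()
        self.a1, self.a2, self.a3 = self.constants.for_na(spectra.probe.na)

    # -- internals --------------------------------------------------------
    def _r0_model(self, params: np.ndarray) -> np.ndarray:
        """Stacked model reflectance for parameter vector (a, b, psb...)."""
        a, b = params[0], params[1]
        psb = params[2:]
        wl = self.spectra.wavelengths
        musp = a * (wl / self.lambda0) ** (-b)
        out = []
        for d_um in self.spectra.diameters_um:
            musp_d = musp * d_um * 1e-4
            out.append(_forward_r0(psb, musp_d, self.spectra.probe,
                                   self.a1, self.a2, self.a3))
        return np.concatenate(out)

    def _observed(self) -> np.ndarray:
        return np.concatenate([self.spectra.reflectance[d]
                               for d in self.spectra.diameters_um])

    def _initial_guess(self, a0: float, b0: float) -> np.ndarray:
        """psb start: invert the semiballistic ratio at the larger diameter."""
        wl = self.spectra.wavelengths
        d_um = self.spectra.diameters_um[-1]
        musp_d = a0 * (wl / self.lambda0) ** (-b0) * d_um * 1e-4
        r0 = self.spectra.reflectance[d_um]
        rdif = collection_efficiency(self.spectra.probe, self.a1) \
            * diffuse_reflectance_fast(musp_d, self.spectra.probe.A)
        x = np.maximum(r0 / rdif - 1.0, 1e-6)
        psb0 = (x / self.a2) ** (1.0 / self.a3) * musp_d ** 2
        return np.concatenate([[a0, b0], np.clip(psb0, 1e-8, 1.0)])

    def _coarse_start(self, a_grid=None, b_grid=None) -> tuple[float, float]:
        """Profile grid search for a robust (a, b) starting point.

        For each candidate power law, psb is profiled out per wavelength by
        inverting the semiballistic ratio on the larger-diameter spectrum;
        the score is the squared relative misfit on the smaller diameter.
        Cheap (vectorized spline R_dif) and immune to the local minima a
        cold start can fall into.
        """
        if a_grid is None:
            a_grid = np.geomspace(2.0, 120.0, 25)
        if b_grid is None:
            b_grid = np.linspace(0.0, 3.0, 13)
        wl = self.spectra.wavelengths
        d_small, d_large = self.spectra.diameters_um
        r_small = self.spectra.reflectance[d_small]
        r_large = self.spectra.reflectance[d_large]
        probe = self.spectra.probe
        eta = collection_efficiency(probe, self.a1)
        scored = []
        for a in a_grid:
            for b in b_grid:
                musp = a * (wl / self.lambda0) ** (-b)
                md_l = musp * d_large * 1e-4
                md_s = musp * d_small * 1e-4
                x_l = np.maximum(r_large / (eta * diffuse_reflectance_fast(
                    md_l, probe.A)) - 1.0, 1e-9)
                psb = (x_l / self.a2) ** (1.0 / self.a3) * md_l ** 2
                x_s = self.a2 * (psb / md_s ** 2) ** self.a3
                pred_s = (1.0 + x_s) * eta * diffuse_reflectance_fast(
                    md_s, probe.A)
                score = float(np.sum((pred_s / r_small - 1.0) ** 2))
                scored.append((score, float(a), float(b)))
        scored.sort()
        return [(a, b) for _, a, b in scored]

    def _jac_sparsity(self):
        n = self.spectra.n_wavelengths
        m = 2 * n
        sp = lil_matrix((m, n + 2), dtype=np.int8)
        sp[:, 0] = 1
        sp[:, 1] = 1
        for i in range(n):
            sp[i, 2 + i] = 1
            sp[n + i, 2 + i] = 1
        return sp

    # -- fitting -----------------------------------------------------------
    def fit(self, initial_guess: tuple[float, float] | None = None,
            bounds: tuple | None = None,
            max_nfev: int = 3000) -> "MDSFRResults":
        """Run the inversion; returns an :class:`MDSFRResults`.

        ``initial_guess`` is ``(a0, b0)``; when omitted, a coarse profile
        grid search chooses it.  Per-wavelength psb starting values are
        derived from the larger-diameter spectrum.  ``bounds`` optionally
        overrides the default positivity bounds as a pair of
        parameter-vector bounds arrays.
        """
        obs = self._observed()
        if initial_guess is not None:
            starts = [tuple(initial_guess)]
        else:
            # deduplicate near-identical candidates; keep up to 6 basins
            starts = []
            for a0, b0 in self._coarse_start():
                if all(abs(np.log(a0 / a1)) > 0.15 or abs(b0 - b1) > 0.3
                       for a1, b1 in starts):
                    starts.append((a0, b0))
                if len(starts) == 6:
                    break
        n = self.spectra.n_wavelengths
        if bounds is None:
            lo = np.concatenate([[1e-2, -4.0], np.full(n, 1e-10)])
            hi = np.concatenate([[1e4, 4.0], np.full(n, 1.0)])
            bounds = (lo, hi)

        def residual(p):
            return self._r0_model(p) / obs - 1.0

        best = None
        agreeing = 0
        for a0, b0 in starts:
            x0 = np.clip(self._initial_guess(a0, b0), bounds[0], bounds[1])
            res = least_squares(residual, x0, bounds=bounds, method="trf",
                                jac_sparsity=self._jac_sparsity(),
                                x_scale="jac", xtol=1e-10, ftol=1e-12,
                                gtol=1e-10, max_nfev=max_nfev)
            if res.status <= 0:
                continue
            if best is not None and res.cost > best.cost * (1.0 - 1e-3):
                agreeing += 1
            if best is None or res.cost < best.cost:
                best = res
            # stop early at a machine-noise fit or a confirmed optimum
            if np.sqrt(2.0 * best.cost / obs.size) < 1e-8 or agreeing >= 2:
                break
        if best is None:
            raise RuntimeError(
                "spectral fit did not converge from any starting point "
                f"(last optimizer message: {res.message})")
        return MDSFRResults(model=self, opt=best)


class MDSFRResults:
    """Estimates, uncertainties and diagnostics of an MDSFR inversion."""

    def __init__(self, model: MDSFRModel, opt):
        self.model = model
        self._opt = opt
        self.params = opt.x
        self.success = bool(opt.success)
        n = model.spectra.n_wavelengths
        self.power_law = ScatteringPowerLaw(a=float(opt.x[0]), b=float(opt.x[1]),
                                            lambda0=model.lambda0)
        self.psb = opt.x[2:]
        self.nobs = 2 * n
        self.df_resid = self.nobs - opt.x.size
        self._cov = self._covariance()
        self.bse = np.sqrt(np.diag(self._cov))

    def _covariance(self) -> np.ndarray:
        jac = np.asarray(self._opt.jac.todense()) if hasattr(self._opt.jac, "todense") \
            else self._opt.jac
        _, s, vt = np.linalg.svd(jac, full_matrices=False)
        s = np.where(s > s.max() * 1e-12, s, np.inf)
        cov = vt.T @ np.diag(1.0 / s ** 2) @ vt
        sigma2 = 2.0 * self._opt.cost / max(self.df_resid, 1)
        return cov * sigma2

    # -- accessors ---------------------------------------------------------
    @property
    def a(self) -> float:
        return self.power_law.a

    @property
    def b(self) -> float:
        return self.power_law.b

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        from scipy.stats import norm

        z = norm.ppf(1.0 - alpha / 2.0)
        return np.column_stack([self.params - z * self.bse,
                                self.params + z * self.bse])

    def musp(self, wavelengths_nm=None) -> np.ndarray:
        wl = self.model.spectra.wavelengths if wavelengths_nm is None \
            else wavelengths_nm
        return self.power_law.musp(wl)

    def fittedvalues(self) -> dict[float, np.ndarray]:
        stacked = self.model._r0_model(self.params)
        n = self.model.spectra.n_wavelengths
        return {d: stacked[i * n:(i + 1) * n]
                for i, d in enumerate(self.model.spectra.diameters_um)}

    def residuals(self) -> dict[float, np.ndarray]:
        """Relative residuals (model/measured - 1) per diameter."""
        fitted = self.fittedvalues()
        return {d: fitted[d] / self.model.spectra.reflectance[d] - 1.0
                for d in self.model.spectra.diameters_um}

    def psb_frame(self) -> pd.DataFrame:
        n = self.model.spectra.n_wavelengths
        return pd.DataFrame({
            "wavelength_nm": self.model.spectra.wavelengths,
            "psb": self.psb,
            "psb_se": self.bse[2:],
        })

    def summary(self) -> str:
        ci = self.conf_int()
        res = self.residuals()
        lines = [
            "Multidiameter single-fiber reflectance inversion",
            "=" * 52,
            f"wavelengths: {self.model.spectra.n_wavelengths}  "
            f"diameters (um): {self.model.spectra.diameters_um}  "
            f"NA: {self.model.spectra.probe.na}",
            f"observations: {self.nobs}   parameters: {self.params.size}   "
            f"dof: {self.df_resid}",
            "",
            f"scattering amplitude a = {self.a:.4g} 1/cm   "
            f"[{ci[0, 0]:.4g}, {ci[0, 1]:.4g}]",
            f"scattering slope     b = {self.b:.4g}        "
            f"[{ci[1, 0]:.4g}, {ci[1, 1]:.4g}]",
            f"psb range: {self.psb.min():.3g} .. {self.psb.max():.3g}",
        ]
        for d in self.model.spectra.diameters_um:
            lines.append(
                f"rms relative residual (d={d:g} um): "
                f"{100 * np.sqrt(np.mean(res[d] ** 2)):.2f}%")
        return "\n".join(lines)
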