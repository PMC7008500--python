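"""Derivation experiments for the semiballistic reflectance model.

Three experiments turn Monte Carlo ensembles into the model's ingredients:

1. *Angle optimization.*  For an ensemble of phase functions simulated at
   ``mu_s' d = 0.1``, scan all backward/forward integration-angle pairs of
   ``Rp(theta_b, theta_f)`` and pick the pair minimizing the mean relative
   dispersion of ``log10 Rp`` at fixed reflectance.  The *relative
   dispersion* for a target reflectance is the spread (max - min) of
   ``log10`` of the parameter among simulations whose reflectance falls
   within +/-10% of the target, divided by the spread over the whole
   ensemble; it is invariant under rescaling of the parameter and bounded
   by [0, 1].

2. *Calibration.*  Fit the constants ``a1`` (collection-efficiency scale)
   and ``a2, a3`` (semiballistic ratio) per numerical aperture by least
   squares on ``log10 R0`` against Monte Carlo reflectances, then fix a
   single shared ``a1`` and refit ``a2, a3``.

3. *Error statistics.*  Median/std/max of the relative prediction error
   against a Monte Carlo reference ensemble, for this model and for the
   gamma-based comparison model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .diffuse import ProbeConfig, collection_efficiency, diffuse_reflectance_fast
from .forward import MUSP_D_VALIDITY_LIMIT
from .phase_functions import PhaseFunction
from .subdiffuse import AnglePair

__all__ = [
    "stratify_by_psb",
    "relative_dispersion",
    "dispersion_targets",
    "scan_integration_angles",
    "DispersionScan",
    "CalibrationResult",
    "calibrate_constants",
    "error_statistics",
]


def stratify_by_psb(grid, n: int) -> list[int]:
    """Indices of ``n`` grid models equally spaced in log-sorted psb order.

    Mirrors the reference protocol of picking simulations whose reflectances
    span the ensemble range in equal logarithmic steps (reflectance at fixed
    ``mu_s'd`` is monotone in psb to good approximation).
    """
    from .subdiffuse import psb as _psb

    vals = np.array([_psb(m) for m in grid.models])
    order = np.argsort(vals)
    return [int(i) for i in order[np.linspace(0, order.size - 1, n).astype(int)]]


def relative_dispersion(r0_values, param_values, target_r0: float,
                        tolerance_fraction: float = 0.10) -> float:
    """Spread of ``log10(param)`` at fixed reflectance over its total spread.

    ``target_r0`` selects the band ``[target*(1-tol), target*(1+tol)]``; at
    least two simulations must fall inside it.
    """
    r0 = np.asarray(r0_values, dtype=float)
    p = np.asarray(param_values, dtype=float)
    if r0.shape != p.shape:
        raise ValueError("r0_values and param_values must have equal length")
    if np.any(p <= 0):
        raise ValueError("param_values must be positive (log10 dispersion)")
    band = (r0 >= target_r0 * (1.0 - tolerance_fraction)) & \
           (r0 <= target_r0 * (1.0 + tolerance_fraction))
    if band.sum() < 2:
        raise ValueError(
            f"fewer than 2 simulations within +/-{tolerance_fraction:.0%} of "
            f"target reflectance {target_r0:g}")
    logp = np.log10(p)
    full = logp.max() - logp.min()
    if full == 0.0:
        return 0.0
    return float((logp[band].max() - logp[band].min()) / full)


def dispersion_targets(r0_values, n_targets: int = 5,
                       quantiles: tuple[float, float] = (0.05, 0.95)
                       ) -> np.ndarray:
    """Target reflectances equally spaced in log10 between two quantiles."""
    r0 = np.asarray(r0_values, dtype=float)
    lo, hi = np.quantile(r0, quantiles)
    return np.logspace(np.log10(lo), np.log10(hi), n_targets)


@dataclass(frozen=True)
class DispersionScan:
    """Result of the integration-angle scan."""

    optimum: AnglePair
    mean_dispersion_at_optimum: float
    surface: pd.DataFrame  # columns theta_b, theta_f, mean_dispersion
    targets: np.ndarray

    def dispersion_vs_theta_b(self) -> pd.DataFrame:
        """Slice of the surface at the optimal forward angle."""
        sel = self.surface[self.surface.theta_f == self.optimum.theta_f]
        return sel.sort_values("theta_b").reset_index(drop=True)

    def dispersion_vs_theta_f(self) -> pd.DataFrame:
        sel = self.surface[self.surface.theta_b == self.optimum.theta_b]
        return sel.sort_values("theta_f").reset_index(drop=True)


def scan_integration_angles(models: list[PhaseFunction], r0_values,
                            theta_b_max: float = 90.0,
                            theta_f_max: float = 89.0,
                            step: float = 1.0,
                            n_targets: int = 5,
                            tolerance_fraction: float = 0.10,
                            target_quantiles: tuple[float, float] = (0.05, 0.95)
                            ) -> DispersionScan:
    """Find the (theta_b, theta_f) minimizing mean relative dispersion.

    ``r0_values`` are the simulated reflectances of ``models`` (same order)
    at the subdiffuse operating point.  Partial phase-function integrals are
    closed-form, so the scan over all angle pairs in steps of ``step``
    degrees is cheap.  Targets with an empty reflectance band are skipped;
    the mean is over the populated targets.
    """
    r0 = np.asarray(r0_values, dtype=float)
    if len(models) != r0.size:
        raise ValueError("one reflectance per model required")
    theta_b = np.arange(step, theta_b_max + step / 2, step)
    theta_f = np.arange(step, theta_f_max + step / 2, step)

    pb = np.array([[m.partial_integral(np.deg2rad(tb), "backward")
                    for tb in theta_b] for m in models])
    pf = np.array([[m.partial_integral(np.deg2rad(tf), "forward")
                    for tf in theta_f] for m in models])

    targets = dispersion_targets(r0, n_targets, target_quantiles)
    bands = [
        (r0 >= t * (1 - tolerance_fraction)) & (r0 <= t * (1 + tolerance_fraction))
        for t in targets
    ]
    bands = [b for b in bands if b.sum() >= 2]
    if not bands:
        raise ValueError("no reflectance target has >= 2 simulations in band")

    # log10 Rp for every model x angle pair: log10 pb - log10(1 - pf)
    log_pb = np.log10(pb)                      # (n_models, n_b)
    log_denom = np.log10(1.0 - pf)             # (n_models, n_f)
    mean_disp = np.zeros((theta_b.size, theta_f.size))

    def _ranges(mask):
        lp = log_pb[mask][:, :, None] - log_denom[mask][:, None, :]
        return lp.max(axis=0), lp.min(axis=0)

    full_max, full_min = _ranges(np.ones(r0.size, dtype=bool))
    full_range = full_max - full_min
    full_range[full_range == 0.0] = np.inf
    for b in bands:
        bmax, bmin = _ranges(b)
        mean_disp += (bmax - bmin) / full_range
    mean_disp /= len(bands)

    i, j = np.unravel_index(np.argmin(mean_disp), mean_disp.shape)
    tb_grid, tf_grid = np.meshgrid(theta_b, theta_f, indexing="ij")
    surface = pd.DataFrame({
        "theta_b": tb_grid.ravel(),
        "theta_f": tf_grid.ravel(),
        "mean_dispersion": mean_disp.ravel(),
    })
    return DispersionScan(
        optimum=AnglePair(float(theta_b[i]), float(theta_f[j])),
        mean_dispersion_at_optimum=float(mean_disp[i, j]),
        surface=surface,
        targets=targets,
    )


@dataclass(frozen=True)
class CalibrationResult:
    """Two-stage calibration of (a1, a2, a3) per numerical aperture.

    ``stage1`` fits all three constants independently per NA; ``stage2``
    fixes the shared ``a1`` and refits ``(a2, a3)``.  Confidence intervals
    are 95% half-widths from the fit covariance.
    """

    stage1: pd.DataFrame  # index NA; a1, a2, a3 and *_ci columns
    stage2: pd.DataFrame  # index NA; a2, a3 and *_ci columns
    a1_shared: float
    residual_rms_log10: dict

    def summary(self) -> str:
        lines = ["Calibration of the semiballistic reflectance model",
                 "=" * 52,
                 "Stage 1 (a1, a2, a3 free per NA):",
                 self.stage1.to_string(float_format=lambda v: f"{v:.4g}"),
                 "",
                 f"Stage 2 (shared a1 = {self.a1_shared:.3f}):",
                 self.stage2.to_string(float_format=lambda v: f"{v:.4g}")]
        return "\n".join(lines)


def _model_log10_r0(params, psb, musp_d, probe, rdif):
    a1, a2, a3 = params
    x = a2 * (psb / musp_d ** 2) ** a3
    eta = collection_efficiency(probe, a1)
    return np.log10((1.0 + x) * eta * rdif)


def _fit_ci(res, n_obs):
    """95% half-widths from a least_squares result."""
    _, s, vt = np.linalg.svd(res.jac, full_matrices=False)
    cov = vt.T @ np.diag(1.0 / s ** 2) @ vt
    dof = max(n_obs - res.x.size, 1)
    sigma2 = 2.0 * res.cost / dof
    return 1.96 * np.sqrt(np.diag(cov) * sigma2)


def calibrate_constants(data: pd.DataFrame,
                        probes: dict[float, ProbeConfig],
                        a1_shared: float | None = None) -> CalibrationResult:
    """Fit model constants to a Monte Carlo ensemble.

    ``data`` needs columns ``na``, ``psb``, ``musp_d``, ``r0``; rows with
    ``musp_d`` below the validity limit are ignored.  The objective is least
    squares on ``log10 R0`` (errors are relative and span decades).  If
    ``a1_shared`` is None, stage 2 uses the stage-1 mean rounded to two
    decimals.
    """
    req = {"na", "psb", "musp_d", "r0"}
    if not req.issubset(data.columns):
        raise ValueError(f"data must have columns {sorted(req)}")
    data = data[data.musp_d >= MUSP_D_VALIDITY_LIMIT]

    stage1_rows, resid = {}, {}
    fits = {}
    for na, sub in data.groupby("na"):
        probe = probes[na]
        psb = sub.psb.to_numpy()
        musp_d = sub.musp_d.to_numpy()
        logr0 = np.log10(sub.r0.to_numpy())
        rdif = diffuse_reflectance_fast(musp_d, probe.A)

        def residual(p):
            return _model_log10_r0(p, psb, musp_d, probe, rdif) - logr0

        res = least_squares(residual, x0=[1.0, 3000.0, 0.75],
                            bounds=([1e-3, 1e-3, 1e-3], [10.0, 1e6, 5.0]),
                            method="trf", xtol=1e-12, ftol=1e-12)
        if not res.success:
            raise RuntimeError(f"stage-1 calibration failed for NA={na}: "
                               f"{res.message}; residual norm {res.cost:.3g}")
        ci = _fit_ci(res, logr0.size)
        stage1_rows[na] = dict(a1=res.x[0], a1_ci=ci[0], a2=res.x[1],
                               a2_ci=ci[1], a3=res.x[2], a3_ci=ci[2])
        fits[na] = (psb, musp_d, logr0, rdif, probe)
        resid[na] = float(np.sqrt(np.mean(residual(res.x) ** 2)))

    stage1 = pd.DataFrame(stage1_rows).T.rename_axis("na")
    if a1_shared is None:
        a1_shared = round(float(stage1.a1.mean()), 2)

    stage2_rows = {}
    for na, (psb, musp_d, logr0, rdif, probe) in fits.items():
        def residual2(p):
            return _model_log10_r0((a1_shared, p[0], p[1]),
                                   psb, musp_d, probe, rdif) - logr0

        res = least_squares(residual2, x0=[3000.0, 0.75],
                            bounds=([1e-3, 1e-3], [1e6, 5.0]),
                            method="trf", xtol=1e-12, ftol=1e-12)
        if not res.success:
            raise RuntimeError(f"stage-2 calibration failed for NA={na}: "
                               f"{res.message}")
        ci = _fit_ci(res, logr0.size)
        stage2_rows[na] = dict(a2=res.x[0], a2_ci=ci[0],
                               a3=res.x[1], a3_ci=ci[1])
    stage2 = pd.DataFrame(stage2_rows).T.rename_axis("na")
    return CalibrationResult(stage1=stage1, stage2=stage2,
                             a1_shared=float(a1_shared),
                             residual_rms_log10=resid)


def error_statistics(predictions, references,
                     musp_d=None,
                     apply_validity_filter: bool = True) -> dict:
    """Relative-error statistics (%) of predictions against MC references.

    Returns ``{"median": ..., "std": ..., "max": ..., "n": ...}`` of
    ``100 * |R0_model - R0_MC| / R0_MC``.  If ``musp_d`` is given and
    ``apply_validity_filter`` is True, pairs below the validity limit are
    excluded first.
    """
    pred = np.asarray(predictions, dtype=float)
    ref = np.asarray(references, dtype=float)
    if pred.shape != ref.shape:
        raise ValueError("predictions and references must have equal length")
    mask = np.ones(pred.size, dtype=bool)
    if musp_d is not None and apply_validity_filter:
        mask &= np.asarray(musp_d, dtype=float) >= MUSP_D_VALIDITY_LIMIT
    err = 100.0 * np.abs(pred[mask] - ref[mask]) / ref[mask]
    return {
        "median": float(np.median(err)),
        "std": float(np.std(err)),
        "max": float(np.max(err)),
        "n": int(err.size),
    }
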