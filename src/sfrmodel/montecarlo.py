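"""Absorption-free Monte Carlo for an overlapping source/detector fiber.

Photons are launched uniformly over the fiber face with directions inside the
acceptance cone, random-walk through a semi-infinite turbid medium with unit
weights (no absorption, no roulette), and are detected if they re-cross the
fiber face within the acceptance angle ``theta_acc = arcsin(NA/n_sample)``.
The surface applies Fresnel reflection/transmission at the tissue-fiber
interface inside the fiber footprint and the tissue-air interface outside it;
transmitted photons that are not detected are lost.  Photons are terminated
once their distance from the fiber-face center exceeds the termination
distance, which must be validated a posteriori: at least 99.9% of detected
photons must have stayed within 75% of it.

Each detected photon is tagged with its number of scattering events, number
of backscattering events (polar scattering angle > 90 deg), total pathlength
and maximum excursion, and its scattering angles contribute to the
"effective phase function" — the angular histogram of scattering events
experienced by detected photons.  A detected photon with exactly one
backscatter event is *semiballistic*.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from ._mc_kernel import HIST_BIN_DEG, HIST_NBINS, build_sampler_table, run_kernel
from .diffuse import ProbeConfig
from .phase_functions import PhaseFunction

__all__ = [
    "SimulationConfig",
    "SimulationResult",
    "TerminationCheck",
    "run_simulation",
    "run_replicates",
    "effective_phase_function",
    "validate_termination",
    "default_termination_distance",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Inputs of one Monte Carlo run.

    ``termination_distance=None`` selects auto mode: start at
    ``max(50/mu_s', 10 d)`` and double until the a-posteriori check passes.
    ``launch`` is ``"uniform-polar"`` (polar angle uniform on [0, theta_acc];
    the default) or ``"uniform-solid-angle"``.
    """

    model: PhaseFunction
    mus: float
    probe: ProbeConfig
    n_photons: int
    seed: int
    termination_distance: float | None = None
    launch: str = "uniform-polar"

    def __post_init__(self) -> None:
        if self.mus <= 0:
            raise ValueError("mus must be > 0")
        if self.n_photons < 1:
            raise ValueError("n_photons must be >= 1")
        if (self.termination_distance is not None
                and self.termination_distance <= self.probe.d):
            raise ValueError("termination_distance must exceed the fiber diameter")
        if self.launch not in ("uniform-polar", "uniform-solid-angle"):
            raise ValueError(f"unknown launch mode {self.launch!r}")

    @property
    def musp(self) -> float:
        """Reduced scattering coefficient mus * (1 - g1), 1/cm."""
        return self.mus * (1.0 - self.model.moments(1)[1])

    @property
    def musp_d(self) -> float:
        return self.musp * self.probe.d


@dataclass(frozen=True)
class TerminationCheck:
    passed: bool
    q999: float
    limit: float
    termination_distance: float
    recommended: float


@dataclass(frozen=True)
class SimulationResult:
    """Tallies of one Monte Carlo run."""

    config: SimulationConfig
    termination_distance: float
    n_launched: int
    n_detected: int
    n_lost: int
    n_terminated: int
    det_n_scatter: np.ndarray
    det_n_backscatter: np.ndarray
    det_pathlength: np.ndarray
    det_max_distance: np.ndarray
    scatter_angle_histogram: np.ndarray  # normalized, HIST_NBINS bins of 0.25 deg

    @property
    def R0_hat(self) -> float:
        """Detected fraction of launched photons."""
        return self.n_detected / self.n_launched

    @property
    def se(self) -> float:
        """Binomial standard error of ``R0_hat``."""
        p = self.R0_hat
        return math.sqrt(p * (1.0 - p) / self.n_launched)

    @property
    def semiballistic_fraction(self) -> float:
        """Weight fraction of detected photons with exactly one backscatter."""
        if self.n_detected == 0:
            return float("nan")
        return float(np.mean(self.det_n_backscatter == 1))


def default_termination_distance(musp: float, d: float) -> float:
    """Auto-mode starting point ``max(50/mu_s', 10 d)`` (cm)."""
    return max(50.0 / musp, 10.0 * d)


def _run_once(config: SimulationConfig, term: float) -> SimulationResult:
    cdf, mu = config.model._inverse_cdf_table()
    cell_lo = build_sampler_table(cdf, mu)
    probe = config.probe
    cap = max(1024, config.n_photons // 8)
    (n_det, n_lost, n_term, nscat, nback, path, maxd, hist) = run_kernel(
        config.seed, config.n_photons, config.mus, probe.d / 2.0, term,
        probe.theta_acc, probe.n_fiber / probe.n_sample,
        probe.n_external / probe.n_sample,
        cdf, mu, cell_lo, config.launch == "uniform-solid-angle", cap)
    total = hist.sum()
    if total > 0:
        hist = hist / total
    return SimulationResult(
        config=config, termination_distance=term,
        n_launched=config.n_photons, n_detected=int(n_det),
        n_lost=int(n_lost), n_terminated=int(n_term),
        det_n_scatter=nscat, det_n_backscatter=nback,
        det_pathlength=path, det_max_distance=maxd,
        scatter_angle_histogram=hist)


def run_simulation(config: SimulationConfig, max_retries: int = 5) -> SimulationResult:
    """Run one simulation, auto-enlarging the termination distance if needed.

    With an explicit ``termination_distance`` the run is performed once and
    an error is raised if the a-posteriori excursion check fails; in auto
    mode the distance is doubled and the simulation rerun (fresh tallies)
    until the check passes.
    """
    auto = config.termination_distance is None
    term = (default_termination_distance(config.musp, config.probe.d)
            if auto else config.termination_distance)
    for _ in range(max_retries):
        result = _run_once(config, term)
        check = validate_termination(result, term)
        if check.passed:
            return result
        if not auto:
            raise RuntimeError(
                f"termination check failed: 99.9% excursion quantile "
                f"{check.q999:.4g} cm exceeds 0.75 * {term:.4g} cm; rerun "
                f"with termination_distance >= {check.recommended:.4g} cm")
        term *= 2.0
    raise RuntimeError("termination distance did not validate after "
                       f"{max_retries} doublings (last {term / 2:.4g} cm)")


def run_replicates(config: SimulationConfig, n_replicates: int = 3
                   ) -> tuple[list[SimulationResult], float]:
    """Run replicates with derived seeds; returns (results, std/mean of R0).

    The precision protocol requires the relative spread to stay below 2%;
    callers decide whether to enlarge ``n_photons`` when it does not.
    """
    results = [
        run_simulation(replace(config, seed=(config.seed + 7919 * i) % (2 ** 31)))
        for i in range(n_replicates)
    ]
    r0 = np.array([r.R0_hat for r in results])
    rel = float(r0.std(ddof=1) / r0.mean()) if r0.mean() > 0 else float("inf")
    return results, rel


def validate_termination(result: SimulationResult,
                         termination_distance: float) -> TerminationCheck:
    """Check that 99.9% of detected photons stayed within 75% of the limit."""
    if result.det_max_distance.size == 0:
        return TerminationCheck(True, 0.0, 0.75 * termination_distance,
                                termination_distance, termination_distance)
    q999 = float(np.quantile(result.det_max_distance, 0.999))
    limit = 0.75 * termination_distance
    passed = q999 < limit
    recommended = termination_distance if passed else 2.0 * termination_distance
    return TerminationCheck(passed, q999, limit, termination_distance, recommended)


def effective_phase_function(result: SimulationResult,
                             bin_width: float = 1.0
                             ) -> tuple[np.ndarray, np.ndarray]:
    """Angular histogram of scattering events of detected photons.

    Returns ``(bin_centers_deg, frequency)`` with the frequency normalized
    to sum to 1.  ``bin_width`` (degrees) must be a multiple of the internal
    tally resolution (0.25 deg).
    """
    if result.n_detected == 0:
        raise ValueError("no detected photons: effective phase function undefined")
    ratio = bin_width / HIST_BIN_DEG
    if abs(ratio - round(ratio)) > 1e-9 or ratio < 1:
        raise ValueError(
            f"bin_width must be a positive multiple of {HIST_BIN_DEG} deg")
    k = int(round(ratio))
    if HIST_NBINS % k:
        raise ValueError(f"bin_width must divide 180 deg evenly (got {bin_width})")
    hist = result.scatter_angle_histogram.reshape(HIST_NBINS // k, k).sum(axis=1)
    centers = (np.arange(hist.size) + 0.5) * bin_width
    return centers, hist
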