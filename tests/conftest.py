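"""Shared fixtures: phase-function grid and scaled Monte Carlo ensembles.

The Monte Carlo fixtures are session-scoped because they are the expensive
part of the suite; every test that consumes them sees the identical seeded
ensemble.  Problem sizes are scaled for a single CPU: the physics being
checked (semiballistic fractions, diffusion limits, calibration structure)
is assertable at these budgets, with tolerances set accordingly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import sfrmodel as s
from sfrmodel.experiments import stratify_by_psb


@pytest.fixture(scope="session")
def grid():
    return s.build_tissue_grid()


@pytest.fixture(scope="session")
def probe22():
    return s.ProbeConfig(d=0.01, na=0.22)


@pytest.fixture(scope="session")
def subdiffuse_ensemble(grid, probe22):
    """10 stratified models at mu_s'd = 0.1, NA 0.22, 2e5 photons each.

    Returns a DataFrame with one row per model: psb, gamma, R0_hat, result.
    """
    idx = stratify_by_psb(grid, 10)
    rows = []
    for k, i in enumerate(idx):
        model = grid.models[i]
        g1 = grid.moments[i][1]
        cfg = s.SimulationConfig(
            model=model, mus=10.0 / (1.0 - g1), probe=probe22,
            n_photons=200_000, seed=4200 + 17 * k, termination_distance=1.0)
        res = s.run_simulation(cfg)
        rows.append({
            "model_index": i,
            "psb": s.psb(model),
            "gamma": (1.0 - grid.moments[i][2]) / (1.0 - g1),
            "r0": res.R0_hat,
            "result": res,
        })
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def diffusion_limit_result(probe22):
    """Single run deep in the diffuse regime: mu_s'd = 100, NA 0.22."""
    g = 0.01
    cfg = s.SimulationConfig(
        model=s.HenyeyGreenstein(g), mus=1e4 / (1 - g), probe=probe22,
        n_photons=30_000, seed=77, termination_distance=0.1)
    return s.run_simulation(cfg)


@pytest.fixture(scope="session")
def mc_phantom_spectra(grid, probe22):
    """MC-simulated two-diameter spectra of a synthetic scattering phantom.

    Power-law scattering (a = 30 /cm at 600 nm, b = 1.2) with a fixed
    moderate-anisotropy grid phase function; 5 wavelengths, 300- and
    600-um fibers, 250k photons per point.  Returns (SpectrumSet, law).
    """
    from sfrmodel.spectra import ScatteringPowerLaw, SpectrumSet

    candidates = [i for i in range(len(grid))
                  if 0.5 <= grid.moments[i][1] <= 0.6
                  and 2e-5 < s.psb(grid.models[i]) < 8e-5]
    i = candidates[0]
    model, g1 = grid.models[i], grid.moments[i][1]
    law = ScatteringPowerLaw(a=30.0, b=1.2)
    wl = np.linspace(400.0, 900.0, 5)
    refl = {}
    for d_um in (300.0, 600.0):
        r0 = []
        for j, w in enumerate(wl):
            cfg = s.SimulationConfig(
                model=model, mus=law.musp(w) / (1.0 - g1),
                probe=probe22.with_diameter(d_um * 1e-4),
                n_photons=250_000, seed=int(52000 + d_um + 7 * j),
                termination_distance=2.5)
            r0.append(s.run_simulation(cfg).R0_hat)
        refl[d_um] = np.array(r0)
    return SpectrumSet(wavelengths=wl, reflectance=refl, probe=probe22), law


@pytest.fixture(scope="session")
def musp_series_ensemble(grid, probe22):
    """8 stratified models at mu_s'd in {0.1, 1, 5, 9}, NA 0.22.

    The operating points mirror the reference protocol (mu_s' = 10, 100,
    500 /cm at d = 100 um, and 100 /cm at d = 900 um); 40k photons per
    point keeps the whole block under a few minutes.
    """
    idx = stratify_by_psb(grid, 8)
    points = [(0.1, 10.0, 0.01), (1.0, 100.0, 0.01),
              (5.0, 500.0, 0.01), (9.0, 100.0, 0.09)]
    rows = []
    for k, i in enumerate(idx):
        model = grid.models[i]
        g1 = grid.moments[i][1]
        for musp_d, musp, d in points:
            term = min(max(50.0 / musp, 10.0 * d), 1.0)
            cfg = s.SimulationConfig(
                model=model, mus=musp / (1.0 - g1),
                probe=probe22.with_diameter(d), n_photons=40_000,
                seed=9000 + 31 * k + int(musp_d * 10),
                termination_distance=term)
            res = s.run_simulation(cfg)
            rows.append({
                "na": 0.22, "model_index": i, "psb": s.psb(model),
                "gamma": (1.0 - grid.moments[i][2]) / (1.0 - g1),
                "musp_d": musp_d, "d": d, "r0": res.R0_hat,
                "n_detected": res.n_detected,
            })
    return pd.DataFrame(rows)
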