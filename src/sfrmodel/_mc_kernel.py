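"""Numba photon-transport kernel for the overlapping-fiber geometry.

Scalar, single-threaded, absorption-free random walk in a semi-infinite
turbid medium (tissue occupies z > 0, fiber face centered at the origin on
z = 0).  Unit photon weights; termination by distance from the fiber-face
center.  Kept free of Python objects so the whole photon loop compiles to
machine code; scattering angles are drawn from a tabulated inverse CDF with
a uniform-u index table so a draw costs O(1) instead of a binary search.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

#: angular resolution (degrees) of the internal scattering-angle tally
HIST_BIN_DEG = 0.25
HIST_NBINS = int(round(180.0 / HIST_BIN_DEG))

#: cells of the uniform-u index accelerating inverse-CDF sampling
_U_CELLS = 4096

#: per-photon scattering-event buffer (events beyond this are untallied in
#: the angle histogram but still counted; practically unreachable)
_EVENT_BUF = 1 << 20

# photon fates
DETECTED, LOST, TERMINATED = 1, 2, 3


def build_sampler_table(cdf: np.ndarray, mu: np.ndarray):
    """Index table: first CDF knot relevant to each uniform-u cell."""
    u_edges = np.arange(_U_CELLS) / _U_CELLS
    lo = np.clip(np.searchsorted(cdf, u_edges, side="right") - 1,
                 0, cdf.size - 2).astype(np.int64)
    return lo


@njit(cache=True)
def _fresnel(cos_i: float, n_rel: float) -> float:
    """Unpolarized Fresnel reflectance, n_rel = n_transmitted / n_incident."""
    if cos_i > 1.0:
        cos_i = 1.0
    sin_i2 = 1.0 - cos_i * cos_i
    sin_t2 = sin_i2 / (n_rel * n_rel)
    if sin_t2 >= 1.0:
        return 1.0
    cos_t = math.sqrt(1.0 - sin_t2)
    rs = (cos_i - n_rel * cos_t) / (cos_i + n_rel * cos_t)
    rp = (n_rel * cos_i - cos_t) / (n_rel * cos_i + cos_t)
    return 0.5 * (rs * rs + rp * rp)


@njit(cache=True)
def run_kernel(seed, n_photons, mus, radius, term_dist,
               theta_acc, n_fiber_rel, n_ext_rel,
               cdf, mu_grid, cell_lo, uniform_solid_angle, cap):
    """Trace ``n_photons`` photons; returns tallies and per-detected tags.

    Parameters are plain scalars/arrays: ``mus`` (1/cm), ``radius`` and
    ``term_dist`` (cm), ``theta_acc`` (rad), relative indices
    ``n_fiber_rel = n_fiber/n_sample`` and ``n_ext_rel = n_ext/n_sample``,
    and the (cdf, mu, cell index) inverse-CDF tables for the phase function.
    """
    np.random.seed(seed)

    cos_acc = math.cos(theta_acc)
    r2_fib = radius * radius
    t2 = term_dist * term_dist
    two_pi = 2.0 * math.pi
    inv_bin = HIST_NBINS / 180.0
    n_cells = cell_lo.size

    det_nscat = np.zeros(cap, dtype=np.int32)
    det_nback = np.zeros(cap, dtype=np.int32)
    det_path = np.zeros(cap, dtype=np.float64)
    det_maxd = np.zeros(cap, dtype=np.float64)
    det_hist = np.zeros(HIST_NBINS, dtype=np.float64)
    ev_bins = np.empty(_EVENT_BUF, dtype=np.int32)

    n_det = 0
    n_lost = 0
    n_term = 0

    for _ in range(n_photons):
        # launch: uniform over the fiber face, downward within theta_acc
        r0 = radius * math.sqrt(np.random.random())
        phi0 = two_pi * np.random.random()
        x = r0 * math.cos(phi0)
        y = r0 * math.sin(phi0)
        z = 0.0
        if uniform_solid_angle:
            ct = 1.0 - (1.0 - cos_acc) * np.random.random()
        else:
            ct = math.cos(theta_acc * np.random.random())
        st = math.sqrt(1.0 - ct * ct)
        phi = two_pi * np.random.random()
        ux = st * math.cos(phi)
        uy = st * math.sin(phi)
        uz = ct  # +z is into the tissue

        n_scat = 0
        n_back = 0
        path = 0.0
        maxd = 0.0  # squared during the walk
        fate = 0

        while fate == 0:
            s = -math.log(np.random.random()) / mus
            # propagate, handling (possibly repeated) surface encounters
            while s > 0.0:
                if uz < 0.0 and z + uz * s < 0.0:
                    sb = -z / uz
                    x += ux * sb
                    y += uy * sb
                    z = 0.0
                    path += sb
                    s -= sb
                    rr = x * x + y * y
                    if rr > maxd:
                        maxd = rr
                    inside = rr <= r2_fib
                    n_rel = n_fiber_rel if inside else n_ext_rel
                    cos_i = -uz
                    if np.random.random() < _fresnel(cos_i, n_rel):
                        uz = -uz  # internally reflected, keep going
                    else:
                        if inside and cos_i >= cos_acc:
                            fate = DETECTED
                        else:
                            fate = LOST
                        s = 0.0
                else:
                    x += ux * s
                    y += uy * s
                    z += uz * s
                    path += s
                    s = 0.0
                    dd = x * x + y * y + z * z
                    if dd > maxd:
                        maxd = dd
                    if dd > t2:
                        fate = TERMINATED
            if fate != 0:
                break

            # scatter: inverse-CDF draw via the uniform-u cell index
            u = np.random.random()
            j = int(u * n_cells)
            if j >= n_cells:
                j = n_cells - 1
            i = cell_lo[j]
            while cdf[i + 1] < u:
                i += 1
            ct_s = mu_grid[i] + (mu_grid[i + 1] - mu_grid[i]) \
                * (u - cdf[i]) / (cdf[i + 1] - cdf[i])
            if ct_s > 1.0:
                ct_s = 1.0
            elif ct_s < -1.0:
                ct_s = -1.0
            if ct_s < 0.0:
                n_back += 1
            if n_scat < _EVENT_BUF:
                b = int(math.acos(ct_s) * (180.0 / math.pi) * inv_bin)
                if b >= HIST_NBINS:
                    b = HIST_NBINS - 1
                ev_bins[n_scat] = b
            n_scat += 1

            # azimuth via rejection sampling (no trig calls)
            while True:
                v1 = 2.0 * np.random.random() - 1.0
                v2 = 2.0 * np.random.random() - 1.0
                rsq = v1 * v1 + v2 * v2
                if 0.0 < rsq < 1.0:
                    break
            cp = (v1 * v1 - v2 * v2) / rsq
            sp = 2.0 * v1 * v2 / rsq

            st_s = math.sqrt(1.0 - ct_s * ct_s)
            if abs(uz) > 0.99999:
                ux = st_s * cp
                uy = st_s * sp
                uz = ct_s if uz > 0.0 else -ct_s
            else:
                den = math.sqrt(1.0 - uz * uz)
                ux_n = st_s * (ux * uz * cp - uy * sp) / den + ux * ct_s
                uy_n = st_s * (uy * uz * cp + ux * sp) / den + uy * ct_s
                uz_n = -st_s * cp * den + uz * ct_s
                norm = math.sqrt(ux_n * ux_n + uy_n * uy_n + uz_n * uz_n)
                ux = ux_n / norm
                uy = uy_n / norm
                uz = uz_n / norm

        if fate == DETECTED:
            if n_det < cap:
                det_nscat[n_det] = n_scat
                det_nback[n_det] = n_back
                det_path[n_det] = path
                det_maxd[n_det] = math.sqrt(maxd)
            n_det += 1
            m = n_scat if n_scat < _EVENT_BUF else _EVENT_BUF
            for k in range(m):
                det_hist[ev_bins[k]] += 1.0
        elif fate == LOST:
            n_lost += 1
        else:
            n_term += 1

    return (n_det, n_lost, n_term,
            det_nscat[:min(n_det, cap)], det_nback[:min(n_det, cap)],
            det_path[:min(n_det, cap)], det_maxd[:min(n_det, cap)],
            det_hist)
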