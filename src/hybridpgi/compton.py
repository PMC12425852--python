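"""Compton (PGI) image reconstruction on the beam-axis plane.

Two reconstruction routes are provided and tested against each other:

* ``backproject_cones`` — brute-force oracle: every event's Compton cone is
  intersected with the z = 0 plane and a Gaussian-weighted band (width in mm)
  is accumulated around the conic curve.  Strictly non-negative, linear in
  the events.

* ``analytic_invert`` — analytical inversion by spherical polynomial
  expansion.  Each cone event constrains the source direction (seen from the
  imager) to a ring at its Compton half-angle; a ring at angle theta has
  Legendre spectrum P_l(cos theta), so the accumulated ring data can be
  deconvolved degree-by-degree.  The inverse filter collapses to a
  two-argument kernel K(cos theta_e, mu) evaluated at mu = direction dot
  cone axis, which is applied per event and summed — algebraically identical
  to an explicit spherical-harmonic transform but evaluated directly at the
  plane-pixel directions.  Truncation degree (l_max), ring apodization and a
  small-coefficient suppression floor regularize the inversion; the output
  carries negative side-lobes and oscillations that shrink with statistics.

Per-imager images are combined with Monte-Carlo field-of-view sensitivity
weights and per-imager efficiency scales (imager C runs at 0.93 and its
image is divided up accordingly).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial import legendre as npleg
from scipy import ndimage

from .images import GridSpec, Image2D
from .geometry import SetupGeometry

try:  # optional acceleration; the numpy fallback is exact but slower
    import numba

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

__all__ = [
    "compton_half_angle",
    "compton_cos_half_angle",
    "KinematicsError",
    "RegularizationError",
    "backproject_cones",
    "analytic_invert",
    "FovWeights",
    "compute_fov_weights",
    "combine_images",
    "reconstruct_pgi",
]

ELECTRON_REST_KEV = 511.0


class KinematicsError(ValueError):
    pass


class RegularizationError(RuntimeError):
    pass


def compton_cos_half_angle(e_scatter, e_absorber):
    """cos(theta) = 1 - m_e c^2 (1/E_abs - 1/(E_sc + E_abs)); may be outside
    [-1, 1] for kinematically invalid pairs (caller rejects those)."""
    e1 = np.asarray(e_scatter, dtype=float)
    e2 = np.asarray(e_absorber, dtype=float)
    return 1.0 - ELECTRON_REST_KEV * (1.0 / e2 - 1.0 / (e1 + e2))


def compton_half_angle(e_scatter: float, e_absorber: float) -> float:
    """Compton cone half-angle in radians; raises for invalid kinematics."""
    if e_scatter <= 0 or e_absorber <= 0:
        raise KinematicsError("energies must be positive")
    c = float(compton_cos_half_angle(e_scatter, e_absorber))
    if abs(c) > 1.0:
        raise KinematicsError(
            f"kinematically invalid pair: cos(theta) = {c:.4f}")
    return float(np.arccos(c))


def _cone_arrays(cones):
    """Accept a cone DataFrame (selection.CONE_COLUMNS) or a dict of arrays."""
    apex = np.column_stack([np.asarray(cones[k], dtype=float)
                            for k in ("apex_x", "apex_y", "apex_z")])
    axis = np.column_stack([np.asarray(cones[k], dtype=float)
                            for k in ("axis_x", "axis_y", "axis_z")])
    theta = np.asarray(cones["half_angle"], dtype=float)
    return apex, axis, theta


# -- pixel-event kernels -----------------------------------------------------

def _backproject_numpy(px, py, apex, axis, theta, weights, sigma):
    out = np.zeros(px.shape[0])
    chunk = max(1, int(4e6 // max(px.shape[0], 1)))
    for i0 in range(0, len(theta), chunk):
        sl = slice(i0, i0 + chunk)
        v = np.empty((theta[sl].shape[0], px.shape[0], 3))
        v[:, :, 0] = px[None, :] - apex[sl, 0][:, None]
        v[:, :, 1] = py[None, :] - apex[sl, 1][:, None]
        v[:, :, 2] = -apex[sl, 2][:, None]
        r = np.linalg.norm(v, axis=2)
        mu = np.einsum("epk,ek->ep", v, axis[sl]) / r
        alpha = np.arccos(np.clip(mu, -1.0, 1.0))
        d = (alpha - theta[sl][:, None]) * r
        out += weights[sl] @ np.exp(-0.5 * (d / sigma) ** 2)
    return out


def _analytic_numpy(px, py, apex, axis, kb, kernel, mu_grid):
    out = np.zeros(px.shape[0])
    chunk = max(1, int(4e6 // max(px.shape[0], 1)))
    for i0 in range(0, len(kb), chunk):
        sl = slice(i0, min(i0 + chunk, len(kb)))
        v = np.empty((kb[sl].shape[0], px.shape[0], 3))
        v[:, :, 0] = px[None, :] - apex[sl, 0][:, None]
        v[:, :, 1] = py[None, :] - apex[sl, 1][:, None]
        v[:, :, 2] = -apex[sl, 2][:, None]
        r = np.linalg.norm(v, axis=2)
        mu = np.einsum("epk,ek->ep", v, axis[sl]) / r
        for row, b in enumerate(kb[sl]):
            out += np.interp(mu[row], mu_grid, kernel[b])
    return out


if HAVE_NUMBA:

    @numba.njit(cache=False, fastmath=True)
    def _backproject_nb(px, py, apex, axis, theta, weights, sigma):  # pragma: no cover
        npix = px.shape[0]
        out = np.zeros(npix)
        for e in range(theta.shape[0]):
            ax, ay, az = apex[e, 0], apex[e, 1], apex[e, 2]
            dx, dy, dz = axis[e, 0], axis[e, 1], axis[e, 2]
            th = theta[e]
            w = weights[e]
            for p in range(npix):
                vx = px[p] - ax
                vy = py[p] - ay
                vz = -az
                r = np.sqrt(vx * vx + vy * vy + vz * vz)
                mu = (vx * dx + vy * dy + vz * dz) / r
                if mu > 1.0:
                    mu = 1.0
                elif mu < -1.0:
                    mu = -1.0
                d = (np.arccos(mu) - th) * r
                out[p] += w * np.exp(-0.5 * (d / sigma) ** 2)
        return out

    @numba.njit(cache=False, fastmath=True)
    def _analytic_nb(px, py, apex, axis, kb, kernel, mu0, dmu):  # pragma: no cover
        npix = px.shape[0]
        nmu = kernel.shape[1]
        out = np.zeros(npix)
        for e in range(axis.shape[0]):
            ax, ay, az = apex[e, 0], apex[e, 1], apex[e, 2]
            dx, dy, dz = axis[e, 0], axis[e, 1], axis[e, 2]
            row = kernel[kb[e]]
            for p in range(npix):
                vx = px[p] - ax
                vy = py[p] - ay
                vz = -az
                r = np.sqrt(vx * vx + vy * vy + vz * vz)
                mu = (vx * dx + vy * dy + vz * dz) / r
                f = (mu - mu0) / dmu
                j = int(f)
                if j < 0:
                    j = 0
                elif j > nmu - 2:
                    j = nmu - 2
                frac = f - j
                out[p] += row[j] * (1.0 - frac) + row[j + 1] * frac
        return out


def backproject_cones(cones, grid: GridSpec, ring_sigma: float = 3.0,
                      weights=None) -> Image2D:
    """Brute-force cone backprojection onto the z = 0 plane.

    ``ring_sigma`` is the Gaussian band width in mm around each cone's conic
    intersection curve (angular deviation times apex distance).
    """
    apex, axis, theta = _cone_arrays(cones)
    if len(theta) == 0:
        raise ValueError("backprojection needs at least one cone event")
    if weights is None:
        weights = np.ones(len(theta))
    weights = np.asarray(weights, dtype=float)
    gx, gy = np.meshgrid(grid.x_centers, grid.y_centers)
    px, py = gx.ravel(), gy.ravel()
    if HAVE_NUMBA:
        flat = _backproject_nb(px, py, apex, axis, theta, weights,
                               float(ring_sigma))
    else:
        flat = _backproject_numpy(px, py, apex, axis, theta, weights,
                                  float(ring_sigma))
    return Image2D(grid, flat.reshape(grid.ny, grid.nx))


def _inversion_kernel(theta, l_max, floor, ring_sigma_rad, n_mu=2048,
                      n_bins=512):
    """Per-degree inverse filter collapsed to a kernel table K[bin, mu]."""
    cos_t = np.cos(theta)
    ells = np.arange(l_max + 1)
    # per-degree ring response over the event ensemble: for a ring at angle
    # theta each backprojected event contributes P_l(cos theta)^2 per degree
    # (addition theorem averaged over the ring azimuth), so the unbiased
    # inverse filter divides by the ensemble mean of P_l^2
    p_events = npleg.legvander(cos_t, l_max)  # (n_events, l_max+1)
    h = (p_events ** 2).mean(axis=0)
    apod = np.exp(-0.5 * ells * (ells + 1) * ring_sigma_rad ** 2)
    keep = np.abs(h) >= floor * np.abs(h).max()
    if not keep.any():
        raise RegularizationError("all filter coefficients below the floor")
    c = np.zeros(l_max + 1)
    c[keep] = (2.0 * ells[keep] + 1.0) / (4.0 * np.pi) * apod[keep] / h[keep]
    edges = np.linspace(cos_t.min() - 1e-9, cos_t.max() + 1e-9, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    kb = np.clip(np.digitize(cos_t, edges) - 1, 0, n_bins - 1)
    mu_grid = np.linspace(-1.0, 1.0, n_mu)
    p_mu = npleg.legvander(mu_grid, l_max)
    p_c = npleg.legvander(centers, l_max)
    kernel = (p_c * c[None, :]) @ p_mu.T  # (n_bins, n_mu)
    return kb.astype(np.int64), kernel, mu_grid


def analytic_invert(cones, grid: GridSpec, scatter_center=None,
                    l_max: int = 40, floor: float = 1e-3,
                    ring_sigma_deg: float = 2.0,
                    min_events: int = 10) -> Image2D:
    """Spherical-expansion analytical inversion for one imager's cones.

    Each event's cone ring is deconvolved by the per-degree inverse filter
    (Legendre spectrum of the ring ensemble) and the filtered kernel is
    evaluated at the direction from the event's own apex to each plane
    pixel, removing the common-apex parallax.  Output may contain negative
    side-lobes and characteristic oscillations that shrink with statistics.

    ``scatter_center`` is accepted for API symmetry but unused (the per-apex
    evaluation supersedes the common-reference projection).
    """
    apex, axis, theta = _cone_arrays(cones)
    if len(theta) < max(min_events, 1):
        raise ValueError(
            f"analytic inversion needs >= {min_events} events, "
            f"got {len(theta)}")
    if l_max < 0:
        raise ValueError("l_max must be >= 0")
    kb, kernel, mu_grid = _inversion_kernel(
        theta, l_max, floor, np.deg2rad(ring_sigma_deg))
    gx, gy = np.meshgrid(grid.x_centers, grid.y_centers)
    px, py = gx.ravel(), gy.ravel()
    if HAVE_NUMBA:
        flat = _analytic_nb(px, py, apex, axis, kb, kernel,
                            mu_grid[0], mu_grid[1] - mu_grid[0])
    else:
        flat = _analytic_numpy(px, py, apex, axis, kb, kernel, mu_grid)
    return Image2D(grid, flat.reshape(grid.ny, grid.nx))


# -- field-of-view weighting -------------------------------------------------

@dataclass
class FovWeights:
    """Per-imager sensitivity maps on a common grid, max-normalized."""

    maps: dict
    floor: float = 1e-3


def compute_fov_weights(setup: SetupGeometry, grid: GridSpec,
                        n_lattice: tuple = (13, 7), n_photons: int = 2000,
                        seed: int = 0, smooth_px: float = 1.0,
                        pairs: bool = False) -> FovWeights:
    """Monte-Carlo sensitivity maps from isotropic point emitters.

    Point sources on a coarse lattice over the grid emit isotropic photons;
    the detected fraction (ray enters the imager's scatter crystal; with
    ``pairs=True``, both back-to-back photons reach opposite-side crystals)
    is interpolated to the full grid, smoothed and max-normalized.
    """
    from .transport import _ray_box
    from scipy.interpolate import RegularGridInterpolator

    rng = np.random.default_rng(seed)
    x0, x1, y0, y1 = grid.extent
    lx = np.linspace(x0, x1, n_lattice[0])
    ly = np.linspace(y0, y1, n_lattice[1])
    half = max(n_photons // 2, 1)
    z = rng.uniform(-1.0, 1.0, half)
    phi = rng.uniform(0.0, 2.0 * np.pi, half)
    r = np.sqrt(1.0 - z ** 2)
    dirs = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    # close the direction set under the z-flip so mirror-symmetric imagers
    # get exactly mirror-identical maps (variance reduction + exact symmetry)
    dirs = np.vstack([dirs, dirs * np.array([1.0, 1.0, -1.0])])
    n_photons = len(dirs)

    maps = {}
    gx, gy = np.meshgrid(grid.x_centers, grid.y_centers)
    any_detected = False
    for im_id, im in setup.imagers.items():
        coarse = np.zeros((len(ly), len(lx)))
        for iy, yy in enumerate(ly):
            for ix, xx in enumerate(lx):
                origin = np.broadcast_to(
                    np.array([xx, yy, 0.0]), dirs.shape)
                if pairs:
                    _, _, h1 = _ray_box(origin, dirs, im.scatter.lo,
                                        im.scatter.hi)
                    opp = [o for o in setup.imagers.values()
                           if o.side != im.side]
                    h2 = np.zeros(n_photons, dtype=bool)
                    for o in opp:
                        for b in o.crystals:
                            _, _, h = _ray_box(origin, -dirs, b.lo, b.hi)
                            h2 |= h
                    hit = h1 & h2
                else:
                    _, _, hit = _ray_box(origin, dirs, im.scatter.lo,
                                         im.scatter.hi)
                coarse[iy, ix] = hit.mean()
        if coarse.max() > 0:
            any_detected = True
        interp = RegularGridInterpolator((ly, lx), coarse, method="linear",
                                         bounds_error=False, fill_value=0.0)
        vals = interp(np.column_stack([gy.ravel(), gx.ravel()]))
        vals = vals.reshape(grid.ny, grid.nx)
        if smooth_px > 0:
            vals = ndimage.gaussian_filter(vals, smooth_px)
        if vals.max() > 0:
            vals = vals / vals.max()
        maps[im_id] = Image2D(grid, vals)
    if not any_detected:
        raise RuntimeError("no lattice point sees any imager: bad geometry")
    return FovWeights(maps)


def combine_images(images: dict, weights: FovWeights,
                   efficiency_scales: dict | None = None) -> Image2D:
    """Efficiency-corrected, FoV-weighted pixelwise combination.

    combined = sum_i (image_i / eff_i) w_i / sum_i w_i; pixels where the
    weight sum falls below the floor are zeroed.
    """
    ids = list(images)
    first = images[ids[0]]
    for im_id in ids[1:]:
        if not first.same_grid(images[im_id]):
            raise ValueError("images must share a common grid")
    eff = efficiency_scales or {}
    num = np.zeros_like(first.values)
    den = np.zeros_like(first.values)
    for im_id in ids:
        if im_id not in weights.maps:
            raise ValueError(f"no FoV weights for imager {im_id}")
        if not first.same_grid(weights.maps[im_id]):
            raise ValueError("weights must share the image grid")
        w = weights.maps[im_id].values
        num += images[im_id].values / eff.get(im_id, 1.0) * w
        den += w
    out = np.zeros_like(num)
    ok = den >= weights.floor
    out[ok] = num[ok] / den[ok]
    return first.copy_with(out)


def reconstruct_pgi(cones, grid: GridSpec, setup: SetupGeometry,
                    method: str = "backproject", weights: FovWeights = None,
                    ring_sigma: float = 3.0, l_max: int = 40,
                    floor: float = 1e-3, min_events: int = 10) -> Image2D:
    """Convenience pipeline: per-imager reconstruction + weighted combination.

    With ``weights=None`` the per-imager images are summed with equal weight
    (efficiency scales still applied for the analytic route via division).
    """
    import pandas as pd

    if not isinstance(cones, pd.DataFrame):
        raise TypeError("reconstruct_pgi expects a cone-event DataFrame")
    if method == "backproject":
        return backproject_cones(cones, grid, ring_sigma=ring_sigma)
    if method != "analytic":
        raise ValueError(f"unknown method {method!r}")
    per_imager = {}
    for im_id, grp in cones.groupby("imager"):
        if len(grp) < min_events:
            continue
        center = setup.imagers[im_id].scatter.center
        per_imager[im_id] = analytic_invert(grp, grid, center, l_max=l_max,
                                            floor=floor,
                                            min_events=min_events)
    if not per_imager:
        raise ValueError("no imager has enough events for analytic inversion")
    if weights is None:
        total = np.sum([img.values / setup.imagers[i].efficiency_scale
                        for i, img in per_imager.items()], axis=0)
        return Image2D(grid, total)
    eff = {i: setup.imagers[i].efficiency_scale for i in per_imager}
    return combine_images(per_imager, weights, eff)
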