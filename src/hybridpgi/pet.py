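"""PET line-of-response imaging on the beam-axis plane.

Each accepted coincidence defines a straight line of response (LOR) between
the two interaction positions; the LOR is intersected with the z = 0 plane
and the intersections are histogrammed over the PET field of view,
separately for the in-spill and off-spill phases.  LORs parallel to the
plane or intersecting outside the extent are counted as discarded, not
clamped.  No attenuation, scatter or randoms correction is applied.
"""

from __future__ import annotations

import warnings

import numpy as np

from .compton import FovWeights
from .images import GridSpec, Image2D
from .geometry import SetupGeometry

__all__ = [
    "reconstruct_pet",
    "pet_efficiency_correction",
    "build_pet_sensitivity",
    "project_1d",
]


def reconstruct_pet(lors, grid: GridSpec, phase: str = "all",
                    return_discarded: bool = False):
    """Histogram LOR-plane intersections over the grid.

    ``phase`` restricts to 'in' / 'off' spill coincidences ('all' keeps
    everything).  Empty selections yield an empty image with a warning.
    """
    if phase not in ("in", "off", "all"):
        raise ValueError(f"unknown phase filter {phase!r}")
    df = lors if phase == "all" else lors[lors["spill_phase"] == phase]
    n = len(df)
    if n == 0:
        warnings.warn(f"no LORs selected for phase={phase!r}: empty image")
        img = grid.empty()
        return (img, 0) if return_discarded else img
    p1 = df[["x1", "y1", "z1"]].to_numpy(dtype=float)
    p2 = df[["x2", "y2", "z2"]].to_numpy(dtype=float)
    dz = p1[:, 2] - p2[:, 2]
    ok = np.abs(dz) > 1e-12
    t = np.zeros(n)
    t[ok] = p1[ok, 2] / dz[ok]
    pts = p1 + t[:, None] * (p2 - p1)
    x0, x1, y0, y1 = grid.extent
    inside = ok & (pts[:, 0] >= x0) & (pts[:, 0] < x1) \
        & (pts[:, 1] >= y0) & (pts[:, 1] < y1)
    hist, _, _ = np.histogram2d(
        pts[inside, 1], pts[inside, 0],
        bins=[grid.ny, grid.nx], range=[[y0, y1], [x0, x1]])
    img = Image2D(grid, hist)
    discarded = int(n - inside.sum())
    return (img, discarded) if return_discarded else img


def pet_efficiency_correction(image: Image2D, weights,
                              floor: float = 1e-3) -> Image2D:
    """Divide pixelwise by the normalized pair-detection sensitivity.

    ``weights`` is an Image2D sensitivity map or a FovWeights whose maps are
    averaged; pixels below ``floor`` of the maximum sensitivity are zeroed.
    """
    if isinstance(weights, FovWeights):
        maps = list(weights.maps.values())
        sens = np.mean([m.values for m in maps], axis=0)
        wimg = maps[0].copy_with(sens)
    else:
        wimg = weights
    if not image.same_grid(wimg):
        raise ValueError("sensitivity map must share the image grid")
    sens = wimg.values
    smax = sens.max()
    if smax <= 0:
        raise ValueError("sensitivity map is empty")
    out = np.zeros_like(image.values)
    ok = sens >= floor * smax
    out[ok] = image.values[ok] / (sens[ok] / smax)
    return image.copy_with(out)


def build_pet_sensitivity(setup: SetupGeometry, grid: GridSpec,
                          n_lattice: tuple = (13, 7), n_photons: int = 2000,
                          seed: int = 0, smooth_px: float = 1.0) -> Image2D:
    """511 keV pair-detection sensitivity map from MC point emitters."""
    from .compton import compute_fov_weights

    w = compute_fov_weights(setup, grid, n_lattice=n_lattice,
                            n_photons=n_photons, seed=seed,
                            smooth_px=smooth_px, pairs=True)
    sens = np.sum([m.values for m in w.maps.values()], axis=0)
    if sens.max() > 0:
        sens /= sens.max()
    return Image2D(grid, sens)


def project_1d(image: Image2D, axis: str = "x", window: tuple | None = None,
               normalize: bool = False) -> tuple:
    """Sum the image over a transverse window; returns (positions, values).

    ``axis`` names the kept coordinate; ``window`` limits the other one
    (defaults to the full extent).  ``normalize`` scales the profile to a
    maximum of 1, the convention used for comparing modalities.
    """
    if axis not in ("x", "y"):
        raise ValueError("axis must be 'x' or 'y'")
    if axis == "x":
        pos, other = image.x_centers, image.y_centers
        values2d = image.values  # (ny, nx): sum over rows
        sum_axis = 0
    else:
        pos, other = image.y_centers, image.x_centers
        values2d = image.values
        sum_axis = 1
    if window is None:
        sel = np.ones(len(other), dtype=bool)
    else:
        lo, hi = window
        sel = (other >= lo) & (other <= hi)
        if not sel.any():
            raise ValueError("empty transverse window")
    vals = (values2d[sel, :].sum(axis=0) if sum_axis == 0
            else values2d[:, sel].sum(axis=1))
    if normalize:
        m = vals.max()
        if m > 0:
            vals = vals / m
    return pos, vals
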