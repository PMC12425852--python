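"""Simplified photon transport: emission records -> calibrated gamma hits.

This is a deliberately thin stand-in for full Monte-Carlo transport: the
pipeline under test is coincidence selection + reconstruction + statistics,
not interaction physics.  Prompt photons undergo exactly one Compton scatter
in a scatter crystal (angle drawn from the Klein-Nishina law) followed by
full absorption if the scattered photon enters an absorber of the same
imager.  Annihilation photons deposit their full 511 keV in the first
crystal they enter, thinned by a configurable efficiency.  No attenuation,
no inter-imager scatter, no neutron background; an optional uniform random
background is added at the dataset level.

Energy conservation is exact before detector smearing: the scatter deposit
plus the scattered-photon energy equals the incident energy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import SetupGeometry

__all__ = [
    "DetectorResponse",
    "klein_nishina_pdf",
    "sample_klein_nishina",
    "trace_prompt",
    "trace_annihilations",
    "HIT_COLUMNS",
]

ELECTRON_REST_KEV = 511.0
C_MM_PER_NS = 299.792458

HIT_COLUMNS = ("event_id", "imager", "layer", "crystal_index",
               "x_mm", "y_mm", "z_mm", "energy_keV", "time_ns")


@dataclass(frozen=True)
class DetectorResponse:
    """Gaussian detector smearing.

    ``energy_fwhm_511``: fractional FWHM at 511 keV, scaling as 1/sqrt(E);
    ``position_sigma``: per-axis position sigma in mm.  Zero means ideal.
    """

    energy_fwhm_511: float = 0.05
    position_sigma: float = 1.5

    def __post_init__(self):
        if self.energy_fwhm_511 < 0 or self.position_sigma < 0:
            raise ValueError("response parameters must be >= 0")

    def scaled(self, energy_factor: float = 1.0,
               position_factor: float = 1.0) -> "DetectorResponse":
        return DetectorResponse(self.energy_fwhm_511 * energy_factor,
                                self.position_sigma * position_factor)

    def energy_sigma(self, e_kev) -> np.ndarray:
        e = np.asarray(e_kev, dtype=float)
        # fractional FWHM(E) = FWHM(511) * sqrt(511/E)
        return self.energy_fwhm_511 * np.sqrt(ELECTRON_REST_KEV * e) / 2.355

    def smear_energy(self, e_kev, rng) -> np.ndarray:
        if self.energy_fwhm_511 == 0:
            return np.asarray(e_kev, dtype=float)
        e = np.asarray(e_kev, dtype=float)
        return e + rng.normal(0.0, 1.0, e.shape) * self.energy_sigma(e)

    def smear_position(self, p, rng) -> np.ndarray:
        p = np.asarray(p, dtype=float)
        if self.position_sigma == 0:
            return p
        return p + rng.normal(0.0, self.position_sigma, p.shape)


def klein_nishina_pdf(cos_theta, e_kev: float) -> np.ndarray:
    """Unnormalized Klein-Nishina angular density in cos(theta).

    dsigma/dOmega ~ eps^2 (eps + 1/eps - sin^2 theta) with
    eps = E'/E = 1 / (1 + k (1 - cos theta)), k = E / 511 keV.
    """
    c = np.asarray(cos_theta, dtype=float)
    k = e_kev / ELECTRON_REST_KEV
    eps = 1.0 / (1.0 + k * (1.0 - c))
    return eps ** 2 * (eps + 1.0 / eps - (1.0 - c ** 2))


def sample_klein_nishina(e_kev: float, n: int,
                         rng: np.random.Generator) -> np.ndarray:
    """Draw n values of cos(theta) by rejection from the KN density."""
    grid = np.linspace(-1.0, 1.0, 2001)
    fmax = klein_nishina_pdf(grid, e_kev).max() * 1.05
    out = np.empty(n)
    filled = 0
    while filled < n:
        m = max(2 * (n - filled), 64)
        c = rng.uniform(-1.0, 1.0, m)
        keep = rng.uniform(0.0, fmax, m) < klein_nishina_pdf(c, e_kev)
        take = min(keep.sum(), n - filled)
        out[filled:filled + take] = c[keep][:take]
        filled += take
    return out


def _ray_box(origins: np.ndarray, dirs: np.ndarray, lo, hi):
    """Vectorized slab test: (t_entry, t_exit, hit) for t >= 0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = 1.0 / dirs
        t1 = (lo[None, :] - origins) * inv
        t2 = (hi[None, :] - origins) * inv
    tmin = np.nanmax(np.minimum(t1, t2), axis=1)
    tmax = np.nanmin(np.maximum(t1, t2), axis=1)
    tmin = np.maximum(tmin, 0.0)
    hit = tmax > tmin
    return tmin, tmax, hit


def _first_box_hit(origins, dirs, boxes):
    """Index of the nearest intersected box (-1 if none) plus entry/exit t."""
    n = origins.shape[0]
    best = np.full(n, np.inf)
    idx = np.full(n, -1, dtype=int)
    t_in = np.zeros(n)
    t_out = np.zeros(n)
    for j, b in enumerate(boxes):
        tmin, tmax, hit = _ray_box(origins, dirs, b.lo, b.hi)
        better = hit & (tmin < best)
        best[better] = tmin[better]
        idx[better] = j
        t_in[better] = tmin[better]
        t_out[better] = tmax[better]
    return idx, t_in, t_out


def _scatter_direction(d, cos_t, rng):
    """Rotate incident directions d by theta with uniform azimuth."""
    n = d.shape[0]
    helper = np.zeros_like(d)
    small_x = np.abs(d[:, 0]) < 0.9
    helper[small_x, 0] = 1.0
    helper[~small_x, 1] = 1.0
    u1 = np.cross(d, helper)
    u1 /= np.linalg.norm(u1, axis=1, keepdims=True)
    u2 = np.cross(d, u1)
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    sin_t = np.sqrt(np.clip(1.0 - cos_t ** 2, 0.0, 1.0))
    s = (cos_t[:, None] * d
         + sin_t[:, None] * (np.cos(phi)[:, None] * u1
                             + np.sin(phi)[:, None] * u2))
    return s / np.linalg.norm(s, axis=1, keepdims=True)


def _hits_frame(records: list) -> pd.DataFrame:
    if not records:
        return pd.DataFrame({c: [] for c in HIT_COLUMNS})
    df = pd.concat(records, ignore_index=True)
    return df.sort_values("time_ns", kind="stable").reset_index(drop=True)


def trace_prompt(origins, dirs, energies, times, event_ids,
                 setup: SetupGeometry, response: DetectorResponse,
                 rng: np.random.Generator,
                 keep_singles: bool = True) -> tuple:
    """Transport prompt photons; returns (hits DataFrame, counts dict).

    Each photon that enters a scatter crystal Compton-scatters once at a
    depth uniform along its chord; the scattered photon is absorbed fully if
    it enters an absorber crystal of the same imager.
    """
    origins = np.atleast_2d(np.asarray(origins, dtype=float))
    dirs = np.atleast_2d(np.asarray(dirs, dtype=float))
    dirs = dirs / np.linalg.norm(dirs, axis=1, keepdims=True)
    energies = np.asarray(energies, dtype=float)
    times = np.asarray(times, dtype=float)
    event_ids = np.asarray(event_ids)

    imager_ids = list(setup.imagers)
    scatter_boxes = [setup.imagers[i].scatter for i in imager_ids]
    idx, t_in, t_out = _first_box_hit(origins, dirs, scatter_boxes)
    hit_mask = idx >= 0
    counts = {"emitted": len(origins), "missed_scatter": int((~hit_mask).sum())}

    o = origins[hit_mask]
    d = dirs[hit_mask]
    e = energies[hit_mask]
    t = times[hit_mask]
    eid = event_ids[hit_mask]
    box_i = idx[hit_mask]
    depth = t_in[hit_mask] + rng.random(hit_mask.sum()) * (
        t_out[hit_mask] - t_in[hit_mask])
    p1 = o + depth[:, None] * d
    t1 = t + depth / C_MM_PER_NS

    # Klein-Nishina angle, sampled per distinct line energy
    cos_t = np.empty(len(e))
    for e_line in np.unique(e):
        m = e == e_line
        cos_t[m] = sample_klein_nishina(e_line, int(m.sum()), rng)
    k = e / ELECTRON_REST_KEV
    e_scattered = e / (1.0 + k * (1.0 - cos_t))
    e_dep = e - e_scattered  # exact energy split before smearing
    s_dir = _scatter_direction(d, cos_t, rng)

    # absorber leg, per imager
    abs_idx = np.full(len(e), -1, dtype=int)
    p2 = np.zeros_like(p1)
    path2 = np.zeros(len(e))
    for j, im_id in enumerate(imager_ids):
        m = box_i == j
        if not m.any():
            continue
        boxes = setup.imagers[im_id].absorbers
        aidx, a_in, a_out = _first_box_hit(p1[m], s_dir[m], boxes)
        got = aidx >= 0
        depth2 = a_in + rng.random(m.sum()) * (a_out - a_in)
        sel = np.where(m)[0]
        abs_idx[sel[got]] = aidx[got]
        p2[sel[got]] = p1[m][got] + depth2[got, None] * s_dir[m][got]
        path2[sel[got]] = depth2[got]
    doublet = abs_idx >= 0
    counts["scatter_only"] = int((~doublet).sum())
    counts["doublets"] = int(doublet.sum())

    im_names = np.array(imager_ids)[box_i]
    records = []
    sc_mask = doublet | keep_singles
    records.append(pd.DataFrame({
        "event_id": eid[sc_mask],
        "imager": im_names[sc_mask],
        "layer": "S",
        "crystal_index": 0,
        "x_mm": response.smear_position(p1[sc_mask, 0], rng),
        "y_mm": response.smear_position(p1[sc_mask, 1], rng),
        "z_mm": response.smear_position(p1[sc_mask, 2], rng),
        "energy_keV": response.smear_energy(e_dep[sc_mask], rng),
        "time_ns": t1[sc_mask],
    }))
    records.append(pd.DataFrame({
        "event_id": eid[doublet],
        "imager": im_names[doublet],
        "layer": "A",
        "crystal_index": abs_idx[doublet],
        "x_mm": response.smear_position(p2[doublet, 0], rng),
        "y_mm": response.smear_position(p2[doublet, 1], rng),
        "z_mm": response.smear_position(p2[doublet, 2], rng),
        "energy_keV": response.smear_energy(e_scattered[doublet], rng),
        "time_ns": t1[doublet] + path2[doublet] / C_MM_PER_NS,
    }))
    return _hits_frame(records), counts


def trace_annihilations(origins, dirs, times, event_ids,
                        setup: SetupGeometry, response: DetectorResponse,
                        rng: np.random.Generator,
                        efficiency: float = 0.7) -> tuple:
    """Transport back-to-back 511 keV pairs; full-energy hits, thinned.

    ``dirs`` holds the direction of the first photon of each pair; the
    second flies opposite.  Returns (hits DataFrame, counts dict).
    """
    origins = np.atleast_2d(np.asarray(origins, dtype=float))
    dirs = np.atleast_2d(np.asarray(dirs, dtype=float))
    dirs = dirs / np.linalg.norm(dirs, axis=1, keepdims=True)
    times = np.asarray(times, dtype=float)
    event_ids = np.asarray(event_ids)

    crystals = setup.all_crystals()
    records = []
    counts = {"pairs": len(origins), "photon_hits": 0}
    for sign in (+1.0, -1.0):
        d = sign * dirs
        idx, t_in, t_out = _first_box_hit(origins, d, crystals)
        m = idx >= 0
        if efficiency < 1.0:
            m &= rng.random(len(idx)) < efficiency
        depth = t_in[m] + rng.random(m.sum()) * (t_out[m] - t_in[m])
        p = origins[m] + depth[:, None] * d[m]
        boxes = [crystals[j] for j in idx[m]]
        counts["photon_hits"] += int(m.sum())
        records.append(pd.DataFrame({
            "event_id": event_ids[m],
            "imager": [b.imager for b in boxes],
            "layer": ["S" if b.role == "scatter" else "A" for b in boxes],
            "crystal_index": [b.index for b in boxes],
            "x_mm": response.smear_position(p[:, 0], rng),
            "y_mm": response.smear_position(p[:, 1], rng),
            "z_mm": response.smear_position(p[:, 2], rng),
            "energy_keV": response.smear_energy(
                np.full(int(m.sum()), ELECTRON_REST_KEV), rng),
            "time_ns": times[m] + depth / C_MM_PER_NS,
        }))
    return _hits_frame(records), counts
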