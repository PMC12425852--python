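"""Bragg-peak and fall-off estimators on 2D images and 1D profiles.

Four estimators, tagged in ``RangeResult.method``:

* ``weighted95`` — intensity-weighted mean x of the 2D pixels above 95% of
  the maximum (ties on the maximum resolved toward the deepest pixel along
  the beam); the uncertainty is the weighted standard deviation of those
  pixels' x.
* ``contour50`` — mean x of the pixels crossing 50% of the maximum beyond
  the peak in the beam direction (value within a band around half-maximum,
  or a sign change between x-neighbours); uncertainty is their x spread.
* ``gaussfit`` — least-squares Gaussian (amplitude, mean, sigma, baseline)
  on a 1D profile with covariance-based parameter errors.
* ``edgefit`` — Gaussian-convolved step (erfc) fit to the distal edge; the
  edge midpoint is the 50% fall-off position.

All estimators are shift-covariant and invariant under positive rescaling
of the intensities.  The beam propagates toward decreasing x by default
(``beam_dir=-1``); negative pixels from the analytical inversion are
clipped to zero before the metrics unless disabled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, special

from .images import Image2D

__all__ = [
    "RangeResult",
    "NoFalloffError",
    "find_max_weighted95",
    "falloff_contour50",
    "fit_gaussian_peak",
    "fit_distal_edge",
    "cross_modality_report",
]


class NoFalloffError(RuntimeError):
    """The profile never falls below 50% of its maximum within the FoV."""


@dataclass(frozen=True)
class RangeResult:
    x_max: float
    x_max_err: float
    x_50: float | None
    x_50_err: float | None
    sigma: float | None
    method: str


def _masked_values(image: Image2D, mask, clip_negative: bool):
    v = image.values.copy()
    if clip_negative:
        np.clip(v, 0.0, None, out=v)
    if mask is not None:
        m = np.asarray(mask, dtype=bool)
        if m.shape != v.shape:
            raise ValueError("mask shape must match the image")
        v = np.where(m, v, 0.0)
    return v


def phantom_mask(image: Image2D, x_range: tuple,
                 y_range: tuple | None = None) -> np.ndarray:
    """Boolean pixel mask selecting the phantom's x (and optionally y) span."""
    xc = image.x_centers[None, :]
    yc = image.y_centers[:, None]
    m = (xc >= x_range[0]) & (xc <= x_range[1])
    m = np.broadcast_to(m, image.values.shape).copy()
    if y_range is not None:
        m &= (yc >= y_range[0]) & (yc <= y_range[1])
    return m


def find_max_weighted95(image: Image2D, mask=None, beam_dir: int = -1,
                        threshold: float = 0.95,
                        clip_negative: bool = True) -> tuple:
    """Weighted >=95%-of-maximum peak position along x; (x_max, x_max_err).

    The anchoring maximum is the highest pixel within the mask, ties broken
    toward the deepest position in the beam direction.
    """
    from scipy import ndimage

    v = _masked_values(image, mask, clip_negative)
    vmax = v.max()
    if vmax <= 0:
        raise ValueError("no positive pixels in the masked image")
    iy, ix = np.where(v == vmax)
    xs = image.x_centers[ix]
    deep = int(np.argmin(xs)) if beam_dir < 0 else int(np.argmax(xs))
    anchor = (iy[deep], ix[deep])
    sel = v >= threshold * vmax
    # keep only the threshold pixels connected to the anchoring maximum so a
    # secondary high-intensity locus elsewhere cannot pull the average
    labels, _ = ndimage.label(sel, structure=np.ones((3, 3), dtype=int))
    sel &= labels == labels[anchor]
    w = v[sel]
    x = np.broadcast_to(image.x_centers[None, :], v.shape)[sel]
    x_mean = float(np.sum(x * w) / np.sum(w))
    var = np.sum(w * (x - x_mean) ** 2) / np.sum(w)
    return x_mean, float(np.sqrt(var))


def falloff_contour50(image: Image2D, x_max: float, mask=None,
                      beam_dir: int = -1, band: float = 0.02,
                      clip_negative: bool = True) -> tuple:
    """Mean x of the 50%-of-maximum contour pixels beyond the peak.

    Contour membership: pixel value within ``band`` (fraction of the
    maximum) of half-maximum, or a strict sign change of v - max/2 between
    x-neighbours (both neighbours join).  Raises ``NoFalloffError`` when no
    pixel qualifies.
    """
    v = _masked_values(image, mask, clip_negative)
    vmax = v.max()
    if vmax <= 0:
        raise ValueError("no positive pixels in the masked image")
    half = 0.5 * vmax
    xc = image.x_centers
    beyond = (xc < x_max) if beam_dir < 0 else (xc > x_max)

    in_band = np.abs(v - half) <= band * vmax
    # sign-change crossings join both neighbours when the crossing interval
    # itself lies beyond the peak (a step between two columns contributes
    # its midpoint)
    d = v - half
    sign_change = d[:, :-1] * d[:, 1:] < 0
    mid_beyond = (0.5 * (xc[:-1] + xc[1:]) < x_max) if beam_dir < 0 \
        else (0.5 * (xc[:-1] + xc[1:]) > x_max)
    pair = sign_change & mid_beyond[None, :]
    crossing = np.zeros_like(in_band)
    crossing[:, :-1] |= pair
    crossing[:, 1:] |= pair
    sel = ((in_band & beyond[None, :]) | crossing) & (v > 0)
    if not sel.any():
        raise NoFalloffError(
            "profile never crosses 50% of maximum beyond the peak")
    x = np.broadcast_to(xc[None, :], v.shape)[sel]
    return float(x.mean()), float(x.std())


def _gauss(x, a, mu, sigma, base):
    return a * np.exp(-0.5 * ((x - mu) / sigma) ** 2) + base


def fit_gaussian_peak(positions, values, sigma=None) -> dict:
    """Gaussian + baseline least-squares fit of a 1D profile.

    Returns mu, sigma, amplitude, baseline and their standard errors from
    the fit covariance (``sigma`` enables a weighted fit).  Raises
    ``RuntimeError`` with diagnostics on non-convergence.
    """
    x = np.asarray(positions, dtype=float)
    y = np.asarray(values, dtype=float)
    if len(x) < 5:
        raise ValueError("need at least 5 points for a Gaussian fit")
    if y.max() <= y.min():
        raise ValueError("profile has no positive peak")
    base0 = float(np.percentile(y, 10))
    a0 = float(y.max() - base0)
    mu0 = float(x[np.argmax(y)])
    w = y - base0
    w = np.clip(w, 0, None)
    sigma0 = float(np.sqrt(np.sum(w * (x - mu0) ** 2) / np.sum(w))) or 1.0
    try:
        popt, pcov = optimize.curve_fit(
            _gauss, x, y, p0=[a0, mu0, sigma0, base0], maxfev=10000,
            sigma=None if sigma is None
            else np.clip(np.asarray(sigma, dtype=float), 1e-12, None),
            absolute_sigma=sigma is not None)
    except RuntimeError as err:
        raise RuntimeError(
            f"Gaussian fit did not converge (p0={[a0, mu0, sigma0, base0]}): "
            f"{err}") from err
    perr = np.sqrt(np.clip(np.diag(pcov), 0, None))
    return {"amplitude": popt[0], "mu": popt[1], "sigma": abs(popt[2]),
            "baseline": popt[3], "amplitude_err": perr[0], "mu_err": perr[1],
            "sigma_err": perr[2], "baseline_err": perr[3]}


def _erfc_edge(x, a, d, sigma, base, beam_dir):
    # beam toward -x: intensity high upstream (x > d), falling through d
    arg = (d - x) / (np.sqrt(2.0) * sigma)
    if beam_dir > 0:
        arg = -arg
    return 0.5 * a * special.erfc(arg) + base


def fit_distal_edge(positions, values, beam_dir: int = -1,
                    window_sigmas: float = 5.0, sigma=None) -> dict:
    """Gaussian-convolved step (erfc) fit of the distal fall-off.

    The 50% fall-off position is the fitted edge midpoint d.  The fit is
    windowed from just upstream of the profile maximum to the FoV edge in
    the beam direction to avoid entrance-region contamination.  ``sigma``
    gives per-point standard deviations for a weighted fit (needed when
    efficiency correction makes the bin variances strongly unequal).
    """
    x = np.asarray(positions, dtype=float)
    y = np.asarray(values, dtype=float)
    order = np.argsort(x)
    x, y = x[order], y[order]
    sig = None if sigma is None else np.asarray(sigma, dtype=float)[order]
    ipk = int(np.argmax(y))
    half = 0.5 * (y.max() + np.percentile(y, 5))
    # initial guess for d: first half-max crossing beyond the peak
    if beam_dir < 0:
        distal_x, distal_y = x[:ipk + 1], y[:ipk + 1]
        below = distal_y < half
        d0 = float(distal_x[below][-1]) if below.any() else float(x[0])
    else:
        distal_x, distal_y = x[ipk:], y[ipk:]
        below = distal_y < half
        d0 = float(distal_x[below][0]) if below.any() else float(x[-1])
    if not below.any():
        raise NoFalloffError("no falling distal segment found")
    sigma0 = max(abs(float(x[ipk]) - d0) / 2.0, np.diff(x).mean())
    lo = d0 - window_sigmas * sigma0
    hi = d0 + window_sigmas * sigma0
    if beam_dir < 0:
        sel = x <= min(float(x[ipk]), hi)
        sel &= x >= max(x[0], lo - window_sigmas * sigma0)
    else:
        sel = x >= max(float(x[ipk]), lo)
        sel &= x <= min(x[-1], hi + window_sigmas * sigma0)
    if sel.sum() < 5:
        sel = np.ones_like(x, dtype=bool)
    base0 = float(np.percentile(y[sel], 5))
    a0 = float(y.max() - base0)

    def f(xx, a, d, s, b):
        return _erfc_edge(xx, a, d, s, b, beam_dir)

    popt, pcov = optimize.curve_fit(
        f, x[sel], y[sel], p0=[a0, d0, sigma0, base0], maxfev=20000,
        sigma=None if sig is None else np.clip(sig[sel], 1e-12, None),
        absolute_sigma=sig is not None)
    perr = np.sqrt(np.clip(np.diag(pcov), 0, None))
    return {"x_50": popt[1], "x_50_err": perr[1], "sigma_edge": abs(popt[2]),
            "amplitude": popt[0], "baseline": popt[3]}


def cross_modality_report(table) -> dict:
    """Cross-modality deviations from a tidy table of peak positions.

    ``table`` is a DataFrame with columns ``position`` (nominal phantom
    position), ``method`` in {'pgi', 'pet_in', 'pet_off'} and ``x_max``
    (estimated maximum, mm).  Returns per-position in-spill vs off-spill PET
    differences and PGI vs off-spill PET deviations, plus their maxima —
    the comparison arithmetic used to summarize multi-modality agreement.
    """
    import pandas as pd

    piv = table.pivot_table(index="position", columns="method",
                            values="x_max", aggfunc="first")
    out = {"per_position": {}, "max_pet_in_off_diff": None,
           "max_pgi_off_diff": None}
    pet_diffs, pgi_diffs = {}, {}
    for pos, row in piv.iterrows():
        entry = {}
        if pd.notna(row.get("pet_in")) and pd.notna(row.get("pet_off")):
            entry["pet_in_off_diff"] = abs(row["pet_in"] - row["pet_off"])
            pet_diffs[pos] = entry["pet_in_off_diff"]
        if pd.notna(row.get("pgi")) and pd.notna(row.get("pet_off")):
            entry["pgi_off_diff"] = abs(row["pgi"] - row["pet_off"])
            pgi_diffs[pos] = entry["pgi_off_diff"]
        out["per_position"][pos] = entry
    if pet_diffs:
        out["max_pet_in_off_diff"] = max(pet_diffs.values())
    if pgi_diffs:
        out["max_pgi_off_diff"] = max(pgi_diffs.values())
        out["argmax_pgi_off_diff"] = max(pgi_diffs, key=pgi_diffs.get)
    return out
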