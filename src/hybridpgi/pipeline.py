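"""End-to-end convenience pipelines shared by the CLI, the analysis
scripts and the acceptance checks.

These helpers wire the stages together for the two desk-scale scenarios:

* 55 MeV-like protons on the graphite cylinder — narrow, coincident prompt
  and activation loci; used for the variance-vs-statistics scaling study;
* 155 MeV-like protons on the PE block — deep beta+ fall-off edge; used for
  the off-spill PET range-shift recovery.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .activation import SpillClock
from .compton import backproject_cones
from .generate import ScenarioConfig, generate_dataset
from .images import GridSpec
from .metrics import find_max_weighted95, phantom_mask
from .selection import (SelectionConfig, build_pgi_coincidences,
                        build_pet_coincidences)
from .sensitivity import subsample_realizations, variance_scaling_study

__all__ = [
    "graphite_cone_pool",
    "pe_offspill_lors",
    "pet_falloff_estimate",
    "falloff_from_image",
    "band_grid",
    "make_xmax_estimator",
    "variance_ratio_study",
    "sensitivity_tables",
]


def graphite_cone_pool(n_accepted: int, seed: int, position: float = 0.0,
                       shift: float = 0.0, response=None,
                       selection: SelectionConfig | None = None,
                       n_spills: int = 50) -> pd.DataFrame:
    """Accepted Compton cones from the graphite scenario, >= n_accepted.

    Generates prompt-gamma batches through transport and selection until the
    pool is large enough, then truncates to exactly ``n_accepted``.
    """
    selection = selection or SelectionConfig()
    clock = SpillClock()
    pools = []
    got = 0
    eff = 0.15  # initial guess, refined after the first batch
    batch_seed = np.random.SeedSequence(seed)
    tries = 0
    while got < n_accepted and tries < 12:
        n_emit = int(min((n_accepted - got) / eff * 1.2 + 1000, 2.5e6))
        sub = batch_seed.spawn(1)[0]
        cfg = ScenarioConfig(
            species="p", energy_label="55MeV", phantom_position=position,
            phantom_shift=shift, n_spills=n_spills, n_prompt=n_emit,
            n_annihilation=1,
            seed=int(sub.generate_state(1)[0] % (2 ** 31)),
            **({"response": response} if response is not None else {}))
        hits, _ = generate_dataset(cfg)
        cones, report = build_pgi_coincidences(hits, selection, clock)
        pools.append(cones)
        got += len(cones)
        eff = max(len(cones) / n_emit, 0.005)
        tries += 1
    pool = pd.concat(pools, ignore_index=True)
    if len(pool) < n_accepted:
        raise RuntimeError(
            f"could not accumulate {n_accepted} cones (got {len(pool)})")
    return pool.iloc[:n_accepted].reset_index(drop=True)


def pe_offspill_lors(n_accepted: int, seed: int, shift: float = 0.0,
                     response=None,
                     selection: SelectionConfig | None = None,
                     n_spills: int = 40) -> pd.DataFrame:
    """Accepted off-spill LORs from the 155 MeV-like PE scenario."""
    selection = selection or SelectionConfig()
    clock = SpillClock()
    pools = []
    got = 0
    eff = 0.2
    batch_seed = np.random.SeedSequence(seed)
    tries = 0
    while got < n_accepted and tries < 12:
        n_emit = int(min((n_accepted - got) / eff * 1.2 + 1000, 2.5e6))
        sub = batch_seed.spawn(1)[0]
        cfg = ScenarioConfig(
            species="p", energy_label="155MeV", phantom_shift=shift,
            n_spills=n_spills, n_prompt=1, n_annihilation=n_emit,
            seed=int(sub.generate_state(1)[0] % (2 ** 31)),
            **({"response": response} if response is not None else {}))
        hits, _ = generate_dataset(cfg)
        lors, _ = build_pet_coincidences(hits, selection, clock)
        off = lors[lors["spill_phase"] == "off"]
        pools.append(off)
        got += len(off)
        eff = max(len(off) / n_emit, 0.005)
        tries += 1
    pool = pd.concat(pools, ignore_index=True)
    if len(pool) < n_accepted:
        raise RuntimeError(
            f"could not accumulate {n_accepted} off-spill LORs "
            f"(got {len(pool)})")
    return pool.iloc[:n_accepted].reset_index(drop=True)


def pet_falloff_estimate(lors: pd.DataFrame, grid: GridSpec,
                         sensitivity=None, y_window: tuple = (-30.0, 30.0),
                         phase: str = "off",
                         fit_halfwidth: float = 20.0) -> dict:
    """Efficiency-corrected off-spill PET fall-off fit.

    Reconstructs the LOR histogram, divides by the pair-detection
    sensitivity map (computed once per geometry when not supplied), projects
    onto x within ``y_window`` and fits the Gaussian-convolved step (erfc)
    to the distal fall-off with per-bin statistical weights (the efficiency
    division makes bin variances strongly unequal, so an unweighted fit
    would be dominated by the noisiest deep bins).  Returns the fit dict
    plus the sensitivity map used (key 'sensitivity').
    """
    from .generate import ScenarioConfig
    from .pet import build_pet_sensitivity, reconstruct_pet

    if sensitivity is None:
        _, setup, _ = ScenarioConfig(energy_label="155MeV").build()
        sensitivity = build_pet_sensitivity(setup, grid, seed=0,
                                            n_lattice=(41, 9),
                                            n_photons=20_000)
    img = reconstruct_pet(lors, grid, phase=phase)
    fit = falloff_from_image(img, sensitivity, y_window=y_window,
                             fit_halfwidth=fit_halfwidth)
    fit["sensitivity"] = sensitivity
    return fit


def falloff_from_image(raw_image, sensitivity,
                       y_window: tuple = (-30.0, 30.0),
                       fit_halfwidth: float = 20.0) -> dict:
    """Weighted erfc fall-off fit from a raw PET count image.

    Applies the efficiency correction, builds per-bin statistical errors
    (sqrt of raw counts scaled by the correction gain) and fits the distal
    edge in a window around the half-maximum crossing.
    """
    from scipy import ndimage

    from .metrics import fit_distal_edge
    from .pet import pet_efficiency_correction, project_1d

    corrected = pet_efficiency_correction(raw_image, sensitivity, floor=0.08)
    pos, vals = project_1d(corrected, axis="x", window=y_window)
    _, raw = project_1d(raw_image, axis="x", window=y_window)
    # per-bin sigma of the corrected profile: sqrt(raw counts) scaled by
    # the same correction factor (corrected = raw / s)
    with np.errstate(divide="ignore", invalid="ignore"):
        gain = np.where(raw > 0, vals / raw, 0.0)
    sig = np.sqrt(np.clip(raw, 1.0, None)) * np.where(gain > 0, gain,
                                                      np.inf)
    # window the fit around the distal half-max crossing of the smoothed
    # profile so the entrance region stays out of the lever arm
    smooth = ndimage.uniform_filter1d(vals, size=7)
    ipk = int(np.argmax(smooth))
    below = smooth[:ipk + 1] < 0.5 * smooth[ipk]
    d0 = pos[:ipk + 1][below][-1] if below.any() else pos[0]
    sel = ((pos >= d0 - fit_halfwidth) & (pos <= d0 + 2 * fit_halfwidth)
           & np.isfinite(sig))
    return fit_distal_edge(pos[sel], vals[sel], beam_dir=-1, sigma=sig[sel])


def band_grid(center_x: float, half_x: float = 45.0, half_y: float = 20.0,
              pixel_mm: float = 1.0) -> GridSpec:
    """Reduced reconstruction grid around the phantom (desk-scale speed)."""
    nx = int(round(2 * half_x / pixel_mm))
    ny = int(round(2 * half_y / pixel_mm))
    return GridSpec((center_x - half_x, center_x + half_x,
                     -half_y, half_y), nx, ny)


def make_xmax_estimator(pool: pd.DataFrame, grid: GridSpec,
                        phantom_x_range: tuple,
                        ring_sigma: float = 3.0):
    """Closure: event-index subset -> weighted-95% peak x from backprojection."""
    mask_cache = {}

    def estimator(indices) -> float:
        sub = pool.iloc[indices]
        img = backproject_cones(sub, grid, ring_sigma=ring_sigma)
        key = id(grid)
        if key not in mask_cache:
            mask_cache[key] = phantom_mask(img, phantom_x_range)
        x_max, _ = find_max_weighted95(img, mask=mask_cache[key])
        return x_max

    return estimator


def variance_ratio_study(seed: int, n_low: int = 2000, factor: int = 10,
                         m: int = 50, position: float = -60.0,
                         pixel_mm: float = 1.0) -> tuple:
    """Spread-reduction ratio between two statistics levels x``factor`` apart.

    Draws ``m`` disjoint subsets at n_low and at n_low*factor accepted
    Compton events, reconstructs each by cone backprojection, estimates the
    peak by the weighted >=95% procedure, and returns
    (std_low / std_high, summary table).
    """
    levels = (n_low, n_low * factor)
    pool = graphite_cone_pool(m * sum(levels), seed, position=position)
    grid = band_grid(position, pixel_mm=pixel_mm)
    estimator = make_xmax_estimator(pool, grid,
                                    (position - 25.0, position + 25.0))
    table = variance_scaling_study(estimator, len(pool), levels, m,
                                   seed=seed + 1, mode="disjoint")
    stds = table.set_index("level")["std"]
    ratio = float(stds[levels[0]] / stds[levels[1]])
    return ratio, table


def sensitivity_tables(rc) -> tuple:
    """CLI backend: variance-scaling table + permutation q90 table."""
    from .sensitivity import permutation_sensitivity

    scen = rc.scenario
    levels = [int(v) for v in rc.sensitivity.levels]
    m = rc.sensitivity.m_per_level
    position = scen.phantom_position + scen.phantom_shift
    pool = graphite_cone_pool(m * sum(levels), rc.seed, position=position)
    grid = band_grid(position)
    estimator = make_xmax_estimator(pool, grid,
                                    (position - 25.0, position + 25.0))
    scaling = variance_scaling_study(estimator, len(pool), levels, m,
                                     seed=rc.seed + 1,
                                     mode=rc.sensitivity.mode)
    rng = np.random.default_rng(rc.seed + 2)
    rows = []
    for level in levels:
        subsets = subsample_realizations(len(pool), level, m, rng,
                                         mode=rc.sensitivity.mode)
        est = [estimator(s) for s in subsets]
        res = permutation_sensitivity(est)
        rows.append({"level": level, "m": m, "q90_mm": res.q90})
    return scaling, pd.DataFrame(rows)
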