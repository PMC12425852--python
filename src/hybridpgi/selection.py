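"""Coincidence building and the timing/energy selections.

PGI: scatter-absorber pairs within one imager inside a closed +-10 ns
window, accepted when the summed energy lies in 600 keV - 6 MeV and the
absorber deposit alone is >= 600 keV (suppresses pair-production positron
decays and random coincidences), and the pair is kinematically valid
(|cos theta| <= 1).

PET: pairs of hits on opposite sides of the beam axis (any layer) inside a
closed +-10 ns window with summed energy in 0.9 - 1.1 MeV.

Multi-hit ambiguity: for each scatter hit the earliest in-window absorber
hit is kept (stable tie-break on energy, then crystal index); remaining
absorber hits stay available for later scatter hits.  A selection report
counts candidates and every rejection cause so that
accepted + rejected-by-* = candidates is auditable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .activation import SpillClock
from .compton import compton_cos_half_angle

__all__ = [
    "SelectionConfig",
    "classify_spill_phase",
    "build_pgi_coincidences",
    "build_pet_coincidences",
]

CONE_COLUMNS = ("apex_x", "apex_y", "apex_z", "axis_x", "axis_y", "axis_z",
                "half_angle", "e_scatter", "e_absorber", "imager",
                "spill_phase", "time_ns")
LOR_COLUMNS = ("x1", "y1", "z1", "x2", "y2", "z2", "e_sum", "spill_phase",
               "time_ns")


@dataclass(frozen=True)
class SelectionConfig:
    dt_pgi_ns: float = 10.0
    dt_pet_ns: float = 10.0
    pgi_sum_window_kev: tuple = (600.0, 6000.0)
    pgi_absorber_min_kev: float = 600.0
    pet_sum_window_kev: tuple = (900.0, 1100.0)

    def __post_init__(self):
        if self.dt_pgi_ns <= 0 or self.dt_pet_ns <= 0:
            raise ValueError("coincidence windows must be > 0")
        for lo, hi in (self.pgi_sum_window_kev, self.pet_sum_window_kev):
            if not lo < hi:
                raise ValueError("energy windows must be non-empty")


def classify_spill_phase(t_ns, clock: SpillClock):
    """'in' during the spill window, 'off' during the break."""
    scalar = np.isscalar(t_ns)
    phase = np.where(clock.in_spill(t_ns), "in", "off")
    return phase.item() if scalar else phase


def _sorted_hits(hits: pd.DataFrame) -> pd.DataFrame:
    return hits.sort_values(
        ["time_ns", "energy_keV", "crystal_index"],
        kind="stable").reset_index(drop=True)


def build_pgi_coincidences(hits: pd.DataFrame, config: SelectionConfig,
                           clock: SpillClock | None = None) -> tuple:
    """Compton cones from scatter-absorber coincidences; (cones, report)."""
    clock = clock or SpillClock()
    hits = _sorted_hits(hits)
    report = {"candidates": 0, "accepted": 0, "rejected_energy_sum": 0,
              "rejected_absorber_min": 0, "rejected_kinematics": 0,
              "unmatched_scatter": 0}
    lo_w, hi_w = config.pgi_sum_window_kev
    frames = []
    for imager, grp in hits.groupby("imager", sort=True):
        sc = grp[grp["layer"] == "S"]
        ab = grp[grp["layer"] == "A"]
        if sc.empty or ab.empty:
            report["unmatched_scatter"] += len(sc)
            continue
        sc_t = sc["time_ns"].to_numpy()
        ab_t = ab["time_ns"].to_numpy()
        used = np.zeros(len(ab), dtype=bool)
        lo_i = np.searchsorted(ab_t, sc_t - config.dt_pgi_ns, side="left")
        hi_i = np.searchsorted(ab_t, sc_t + config.dt_pgi_ns, side="right")
        # earliest unused absorber hit per scatter hit (stable energy/index
        # tie-break is inherited from the sort)
        match = np.full(len(sc), -1, dtype=int)
        for i in range(len(sc)):
            for j in range(lo_i[i], hi_i[i]):
                if not used[j]:
                    match[i] = j
                    used[j] = True
                    break
        paired = match >= 0
        report["unmatched_scatter"] += int((~paired).sum())
        report["candidates"] += int(paired.sum())
        if not paired.any():
            continue
        s_arr = sc[paired]
        a_arr = ab.iloc[match[paired]]
        e1 = s_arr["energy_keV"].to_numpy()
        e2 = a_arr["energy_keV"].to_numpy()
        bad_abs = e2 < config.pgi_absorber_min_kev
        bad_sum = ~bad_abs & ((e1 + e2 < lo_w) | (e1 + e2 > hi_w))
        cos_t = compton_cos_half_angle(e1, e2)
        bad_kin = ~bad_abs & ~bad_sum & (np.abs(cos_t) > 1.0)
        ok = ~(bad_abs | bad_sum | bad_kin)
        report["rejected_absorber_min"] += int(bad_abs.sum())
        report["rejected_energy_sum"] += int(bad_sum.sum())
        report["rejected_kinematics"] += int(bad_kin.sum())
        report["accepted"] += int(ok.sum())
        if not ok.any():
            continue
        apex = s_arr[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float)[ok]
        axis = apex - a_arr[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float)[ok]
        axis /= np.linalg.norm(axis, axis=1, keepdims=True)
        t_s = s_arr["time_ns"].to_numpy()[ok]
        frames.append(pd.DataFrame({
            "apex_x": apex[:, 0], "apex_y": apex[:, 1], "apex_z": apex[:, 2],
            "axis_x": axis[:, 0], "axis_y": axis[:, 1], "axis_z": axis[:, 2],
            "half_angle": np.arccos(cos_t[ok]),
            "e_scatter": e1[ok], "e_absorber": e2[ok],
            "imager": imager,
            "spill_phase": classify_spill_phase(t_s, clock),
            "time_ns": t_s,
        }))
    if frames:
        frame = pd.concat(frames, ignore_index=True)
    else:
        frame = pd.DataFrame({c: [] for c in CONE_COLUMNS})
    return frame, report


def build_pet_coincidences(hits: pd.DataFrame, config: SelectionConfig,
                           clock: SpillClock | None = None) -> tuple:
    """Cross-side LORs within the PET window; returns (lors, report)."""
    clock = clock or SpillClock()
    hits = _sorted_hits(hits)
    t = hits["time_ns"].to_numpy()
    x = hits["x_mm"].to_numpy()
    y = hits["y_mm"].to_numpy()
    z = hits["z_mm"].to_numpy()
    e = hits["energy_keV"].to_numpy()
    n = len(hits)
    report = {"candidates": 0, "accepted": 0, "rejected_energy_sum": 0,
              "rejected_same_side": 0}
    lors = []
    used = np.zeros(n, dtype=bool)
    hi_i = np.searchsorted(t, t + config.dt_pet_ns, side="right")
    for i in range(n):
        if used[i]:
            continue
        for j in range(i + 1, hi_i[i]):
            if used[j]:
                continue
            report["candidates"] += 1
            if np.sign(z[i]) == np.sign(z[j]):
                report["rejected_same_side"] += 1
                continue
            lo, hi = config.pet_sum_window_kev
            if not lo <= e[i] + e[j] <= hi:
                report["rejected_energy_sum"] += 1
                continue
            used[i] = used[j] = True
            lors.append((x[i], y[i], z[i], x[j], y[j], z[j],
                         e[i] + e[j],
                         classify_spill_phase(float(min(t[i], t[j])), clock),
                         float(min(t[i], t[j]))))
            report["accepted"] += 1
            break
    frame = pd.DataFrame(lors, columns=LOR_COLUMNS)
    return frame, report
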