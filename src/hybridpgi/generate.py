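"""Seeded end-to-end generation of list-mode gamma-hit streams.

One master seed drives everything: submodule generators are spawned from
``numpy.random.SeedSequence(master).spawn(...)`` in a fixed documented order
(prompt sampling, prompt transport, annihilation sampling, annihilation
transport, background), so partial re-runs are reproducible.

Emission channels:

* prompt gammas — depths from the prompt profile, transverse Gaussian beam
  spot, discrete line energies, times uniform within spill windows;
* annihilation pairs — decay times from the per-isotope pulsed-activation
  dynamics, origins from the isotope production profile blurred by the
  positron range, two exactly anti-parallel 511 keV photons;
* optional uniform random background hits during spills.

Directions are importance-aimed at crystal volumes by default (a photon
aimed at a uniform point inside a crystal is guaranteed to intersect it);
this biases only the absolute efficiency, which this generator does not
claim to model, never the cone/LOR geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json

import numpy as np
import pandas as pd

from .activation import SpillClock, sample_decay_times
from .geometry import SetupGeometry, build_default_setup, graphite_cylinder, pe_block
from .profiles import (EmissionModel, ModelError, graphite_55mev_model,
                       pe_155mev_model)
from .transport import (DetectorResponse, trace_prompt, trace_annihilations,
                        _hits_frame, HIT_COLUMNS, ELECTRON_REST_KEV)

__all__ = [
    "ScenarioConfig",
    "sample_prompt_gammas",
    "sample_annihilations",
    "transport_to_hits",
    "generate_dataset",
]


def _isotropic(n: int, rng: np.random.Generator) -> np.ndarray:
    z = rng.uniform(-1.0, 1.0, n)
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    r = np.sqrt(1.0 - z ** 2)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _aimed(origins: np.ndarray, setup: SetupGeometry,
           rng: np.random.Generator, scatter_only: bool) -> np.ndarray:
    """Directions toward uniform points inside random crystals."""
    if scatter_only:
        boxes = [im.scatter for im in setup.imagers.values()]
    else:
        boxes = setup.all_crystals()
    pick = rng.integers(0, len(boxes), len(origins))
    lo = np.array([b.lo for b in boxes])
    hi = np.array([b.hi for b in boxes])
    target = lo[pick] + rng.random((len(origins), 3)) * (hi[pick] - lo[pick])
    d = target - origins
    return d / np.linalg.norm(d, axis=1, keepdims=True)


def _spill_times(n: int, clock: SpillClock, n_spills: int,
                 rng: np.random.Generator) -> np.ndarray:
    """Emission times (ns) uniform within the spill windows."""
    spill = rng.integers(0, n_spills, n)
    return spill * clock.period_ns + rng.random(n) * clock.spill_ns


def sample_prompt_gammas(model: EmissionModel, n: int, clock: SpillClock,
                         n_spills: int, rng: np.random.Generator) -> pd.DataFrame:
    """n prompt-gamma emissions: origin, line energy, in-spill time."""
    if n <= 0:
        raise ModelError("n must be > 0")
    x = model.prompt_profile.sample(n, rng)
    y = rng.normal(0.0, model.beam_sigma_transverse, n)
    z = rng.normal(0.0, model.beam_sigma_transverse, n)
    lines = np.array([e for e, _ in model.prompt_lines])
    weights = np.array([w for _, w in model.prompt_lines])
    e = lines[rng.choice(len(lines), n, p=weights / weights.sum())]
    t = _spill_times(n, clock, n_spills, rng)
    return pd.DataFrame({"x": x, "y": y, "z": z, "energy_keV": e, "time_ns": t})


def sample_annihilations(model: EmissionModel, clock: SpillClock,
                         n_spills: int, n: int,
                         rng: np.random.Generator) -> pd.DataFrame:
    """n annihilation events with decay times from the spill-train dynamics.

    Isotopes are chosen by yield weight; each isotope's decay times follow
    the activity curve of a constant in-spill production at unit rate with
    its own decay constant.  The returned frame carries the origin, time and
    the direction of the first photon of the back-to-back pair.
    """
    if n_spills < 1:
        raise ModelError("n_spills must be >= 1")
    yields = np.array([iso.yield_weight for iso in model.isotopes])
    pick = rng.choice(len(model.isotopes), n, p=yields / yields.sum())
    x = np.empty(n)
    t = np.empty(n)
    for i, iso in enumerate(model.isotopes):
        m = pick == i
        k = int(m.sum())
        if k == 0:
            continue
        x[m] = iso.production_profile.sample(k, rng)
        t[m] = sample_decay_times(1.0, iso.lam_per_s, clock, n_spills, k, rng)
    blur = model.positron_range_sigma
    origin = np.column_stack([
        x + (rng.normal(0.0, blur, n) if blur > 0 else 0.0),
        rng.normal(0.0, model.beam_sigma_transverse, n)
        + (rng.normal(0.0, blur, n) if blur > 0 else 0.0),
        rng.normal(0.0, model.beam_sigma_transverse, n)
        + (rng.normal(0.0, blur, n) if blur > 0 else 0.0),
    ])
    d = _isotropic(n, rng)
    return pd.DataFrame({
        "x": origin[:, 0], "y": origin[:, 1], "z": origin[:, 2],
        "time_ns": t,
        "dx": d[:, 0], "dy": d[:, 1], "dz": d[:, 2],
        "isotope": [model.isotopes[i].name for i in pick],
    })


def transport_to_hits(emissions: pd.DataFrame, setup: SetupGeometry,
                      response: DetectorResponse, mode: str,
                      rng: np.random.Generator,
                      aim: bool = True, event_id_offset: int = 0) -> tuple:
    """Trace emission records to a GammaHit stream; returns (hits, counts)."""
    n = len(emissions)
    origins = emissions[["x", "y", "z"]].to_numpy()
    ids = np.arange(event_id_offset, event_id_offset + n)
    if mode == "prompt":
        dirs = (_aimed(origins, setup, rng, scatter_only=True) if aim
                else _isotropic(n, rng))
        return trace_prompt(origins, dirs, emissions["energy_keV"].to_numpy(),
                            emissions["time_ns"].to_numpy(), ids, setup,
                            response, rng)
    if mode == "annihilation":
        if aim:
            dirs = _aimed(origins, setup, rng, scatter_only=False)
        elif {"dx", "dy", "dz"}.issubset(emissions.columns):
            dirs = emissions[["dx", "dy", "dz"]].to_numpy()
        else:
            dirs = _isotropic(n, rng)
        return trace_annihilations(origins, dirs,
                                   emissions["time_ns"].to_numpy(), ids,
                                   setup, response, rng)
    raise ValueError(f"unknown transport mode {mode!r}")


def sample_prompt_epoch_pairs(model: EmissionModel, clock: SpillClock,
                              n_spills: int, n: int,
                              rng: np.random.Generator) -> pd.DataFrame:
    """Broad in-spill annihilation background.

    During beam delivery, pair production by high-energy gammas and the
    positrons annihilating in the setup produce 511 keV pairs spread over
    the whole irradiated volume; this component only exists in-spill and is
    what broadens the in-spill PET profile relative to off-spill.  Origins
    are drawn flat over the emission-profile depth range with a wide
    transverse spread.
    """
    prof = model.isotopes[0].production_profile
    x = rng.uniform(prof.x_min, prof.x_max, n)
    origin = np.column_stack([
        x, rng.normal(0.0, 15.0, n), rng.normal(0.0, 15.0, n)])
    t = _spill_times(n, clock, n_spills, rng)
    d = _isotropic(n, rng)
    return pd.DataFrame({
        "x": origin[:, 0], "y": origin[:, 1], "z": origin[:, 2],
        "time_ns": t,
        "dx": d[:, 0], "dy": d[:, 1], "dz": d[:, 2],
        "isotope": "prompt_epoch",
    })


def _background_hits(rate_per_spill: float, clock: SpillClock, n_spills: int,
                     setup: SetupGeometry, response: DetectorResponse,
                     rng: np.random.Generator, offset: int) -> pd.DataFrame:
    """Uniform in-spill random hits across all crystals (flat 100-3000 keV)."""
    n = rng.poisson(rate_per_spill * n_spills)
    if n == 0:
        return pd.DataFrame({c: [] for c in HIT_COLUMNS})
    boxes = setup.all_crystals()
    pick = rng.integers(0, len(boxes), n)
    lo = np.array([b.lo for b in boxes])
    hi = np.array([b.hi for b in boxes])
    p = lo[pick] + rng.random((n, 3)) * (hi[pick] - lo[pick])
    return pd.DataFrame({
        "event_id": np.arange(offset, offset + n),
        "imager": [boxes[j].imager for j in pick],
        "layer": ["S" if boxes[j].role == "scatter" else "A" for j in pick],
        "crystal_index": [boxes[j].index for j in pick],
        "x_mm": p[:, 0], "y_mm": p[:, 1], "z_mm": p[:, 2],
        "energy_keV": rng.uniform(100.0, 3000.0, n),
        "time_ns": _spill_times(n, clock, n_spills, rng),
    })


@dataclass(frozen=True)
class ScenarioConfig:
    """An irradiation scenario in the style of the experimental campaign."""

    species: str = "p"                  # p | He | C
    energy_label: str = "55MeV"         # "55MeV" (graphite) | "155MeV" (PE)
    phantom_shift: float = 0.0          # mm along the beam axis
    phantom_position: float = 0.0       # graphite cylinder center (mm)
    n_spills: int = 100
    n_prompt: int = 200_000             # prompt gammas traced
    n_annihilation: int = 100_000       # annihilation pairs traced
    #: fraction of the annihilation budget spent on the broad in-spill
    #: prompt-epoch pair background (pair production + in-setup positrons);
    #: the published in-spill PET profiles are ~1.5x wider than off-spill,
    #: which this component reproduces at its default share
    inspill_broad_fraction: float = 0.15
    background_rate_per_spill: float = 0.0
    seed: int = 0
    aim: bool = True
    response: DetectorResponse = field(default_factory=DetectorResponse)
    yields: dict | None = None

    def build(self) -> tuple:
        """Returns (EmissionModel, SetupGeometry, SpillClock)."""
        clock = SpillClock()
        if self.energy_label == "55MeV":
            pos = self.phantom_position + self.phantom_shift
            model = graphite_55mev_model(pos, self.yields)
            phantom = graphite_cylinder(pos)
        else:
            model = pe_155mev_model(self.phantom_shift, self.species,
                                    self.yields)
            phantom = pe_block(-20.0 + self.phantom_shift)
        return model, build_default_setup(phantom=phantom), clock


def generate_dataset(config: ScenarioConfig,
                     out_prefix=None) -> tuple:
    """End-to-end generation: returns (hits DataFrame, manifest dict).

    If ``out_prefix`` is given, writes ``<prefix>_hits.csv`` and
    ``<prefix>_manifest.json``.
    """
    model, setup, clock = config.build()
    streams = np.random.SeedSequence(config.seed).spawn(5)
    rngs = [np.random.default_rng(s) for s in streams]

    frames = []
    counts = {}
    prompt = sample_prompt_gammas(model, config.n_prompt, clock,
                                  config.n_spills, rngs[0])
    h, c = transport_to_hits(prompt, setup, config.response, "prompt",
                             rngs[1], aim=config.aim)
    frames.append(h)
    counts["prompt"] = c
    n_broad = int(round(config.inspill_broad_fraction
                        * config.n_annihilation))
    n_true = max(config.n_annihilation - n_broad, 1)
    annih = sample_annihilations(model, clock, config.n_spills, n_true,
                                 rngs[2])
    if n_broad > 0:
        broad = sample_prompt_epoch_pairs(model, clock, config.n_spills,
                                          n_broad, rngs[2])
        annih = pd.concat([annih, broad], ignore_index=True)
    h, c = transport_to_hits(annih, setup, config.response, "annihilation",
                             rngs[3], aim=config.aim,
                             event_id_offset=config.n_prompt)
    frames.append(h)
    counts["annihilation"] = c
    counts["annihilation"]["prompt_epoch_pairs"] = n_broad
    if config.background_rate_per_spill > 0:
        frames.append(_background_hits(
            config.background_rate_per_spill, clock, config.n_spills, setup,
            config.response, rngs[4],
            offset=config.n_prompt + config.n_annihilation))
    hits = _hits_frame(frames)

    prompt_profile = model.prompt_profile
    beta_profile = model.isotopes[0].production_profile
    manifest = {
        "format_version": 1,
        "species": config.species,
        "energy_label": config.energy_label,
        "phantom_shift_mm": config.phantom_shift,
        "phantom_position_mm": config.phantom_position,
        "n_spills": config.n_spills,
        "n_prompt": config.n_prompt,
        "n_annihilation": config.n_annihilation,
        "seed": config.seed,
        "counts": counts,
        "truth": {
            "prompt_peak_x_mm": prompt_profile.peak_position,
            "beta_peak_x_mm": beta_profile.peak_position,
            # 50% fall-off: erfc midpoint for smeared-plateau profiles,
            # half-maximum of the Gaussian peak otherwise
            "beta_falloff_x_mm": (
                beta_profile.plateau_range[0]
                if beta_profile.edge_sigma > 0
                and beta_profile.plateau_range is not None
                else beta_profile.peak_position
                - beta_profile.peak_sigma * np.sqrt(2 * np.log(2))),
            "flash_amplitude": prompt_profile.flash_amplitude,
        },
    }
    if out_prefix is not None:
        from .hitio import write_hits, write_manifest
        write_hits(f"{out_prefix}_hits.csv", hits, manifest)
        write_manifest(f"{out_prefix}_manifest.json", manifest)
    return hits, manifest
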