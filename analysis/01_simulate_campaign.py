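#!/usr/bin/env python
"""Generate the synthetic irradiation campaign.

Emulates the two measurement blocks at desk scale: 55 MeV-like protons on
the graphite cylinder at three positions (0, -60, -120 mm) and 155 MeV-like
protons on the PE block at three sub-mm shifts (0, +1, +1.5 mm).  Writes
one hit stream + manifest per irradiation under scratch/campaign/ (large
regenerable artifacts live under scratch/, derived tables in results/).
"""

import pathlib

from hybridpgi.generate import ScenarioConfig, generate_dataset

OUT = pathlib.Path("scratch/campaign")
OUT.mkdir(parents=True, exist_ok=True)

RUNS = [
    ("graphite_0", ScenarioConfig(energy_label="55MeV", phantom_position=0.0,
                                  n_prompt=400_000, n_annihilation=150_000,
                                  n_spills=100, seed=101)),
    ("graphite_m60", ScenarioConfig(energy_label="55MeV",
                                    phantom_position=-60.0,
                                    n_prompt=400_000, n_annihilation=150_000,
                                    n_spills=100, seed=102)),
    ("graphite_m120", ScenarioConfig(energy_label="55MeV",
                                     phantom_position=-120.0,
                                     n_prompt=400_000,
                                     n_annihilation=150_000,
                                     n_spills=100, seed=103)),
    ("pe_ref", ScenarioConfig(energy_label="155MeV", phantom_shift=0.0,
                              n_prompt=200_000, n_annihilation=400_000,
                              n_spills=100, seed=104)),
    ("pe_p1mm", ScenarioConfig(energy_label="155MeV", phantom_shift=1.0,
                               n_prompt=200_000, n_annihilation=400_000,
                               n_spills=100, seed=105)),
    ("pe_p1p5mm", ScenarioConfig(energy_label="155MeV", phantom_shift=1.5,
                                 n_prompt=200_000, n_annihilation=400_000,
                                 n_spills=100, seed=106)),
]


def main() -> None:
    for name, cfg in RUNS:
        hits, manifest = generate_dataset(cfg, out_prefix=str(OUT / name))
        print(f"{name}: {len(hits)} hits "
              f"(prompt doublets {manifest['counts']['prompt']['doublets']}, "
              f"pair hits {manifest['counts']['annihilation']['photon_hits']})")
    print(f"wrote {len(RUNS)} hit streams under {OUT}/")


if __name__ == "__main__":
    main()
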