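#!/usr/bin/env python
"""Select coincidences and reconstruct PGI and PET images per irradiation.

For every hit stream from 01_simulate_campaign.py: build PGI cones and PET
LORs with the standard selections (10 ns windows; 600 keV-6 MeV sum with
>= 600 keV in the absorber; 0.9-1.1 MeV for PET), reconstruct the combined
Compton image by cone backprojection and the in-spill/off-spill PET
histograms, and write images, 1D projections and selection reports.
"""

import pathlib
import warnings

from hybridpgi.activation import SpillClock
from hybridpgi.compton import backproject_cones
from hybridpgi.hitio import read_hits, write_manifest, write_profile
from hybridpgi.images import GridSpec, write_image
from hybridpgi.pet import project_1d, reconstruct_pet
from hybridpgi.selection import (SelectionConfig, build_pet_coincidences,
                                 build_pgi_coincidences)

CAMPAIGN = pathlib.Path("scratch/campaign")
OUT = pathlib.Path("scratch/images")       # large image matrices
TABLES = pathlib.Path("results/profiles")  # small profiles + reports
OUT.mkdir(parents=True, exist_ok=True)
TABLES.mkdir(parents=True, exist_ok=True)

# reduced pixelations and a per-image event cap keep the whole campaign to a
# couple of minutes; the FoV extents match the full-resolution conventions
PGI_GRID = GridSpec((-250, 250, -250, 250), 200, 200)
PET_GRID = GridSpec((-150, 150, -150, 150), 300, 300)
MAX_CONES_PER_IMAGE = 40_000


def main() -> None:
    clock = SpillClock()
    cfg = SelectionConfig()
    for hits_path in sorted(CAMPAIGN.glob("*_hits.csv")):
        name = hits_path.name.replace("_hits.csv", "")
        hits = read_hits(hits_path)
        cones, pgi_rep = build_pgi_coincidences(hits, cfg, clock)
        lors, pet_rep = build_pet_coincidences(hits, cfg, clock)
        print(f"{name}: {pgi_rep['accepted']} cones, "
              f"{pet_rep['accepted']} LORs "
              f"({(lors['spill_phase'] == 'off').sum()} off-spill)")
        write_manifest(TABLES / f"{name}_selection.json",
                       {"pgi": pgi_rep, "pet": pet_rep})
        if len(cones) > MAX_CONES_PER_IMAGE:
            cones = cones.sample(MAX_CONES_PER_IMAGE, random_state=0)
        img = backproject_cones(cones, PGI_GRID, ring_sigma=3.0)
        write_image(OUT / f"{name}_pgi.txt", img, {"mode": "pgi"})
        pos, vals = project_1d(img, axis="x", window=(-30, 30),
                               normalize=True)
        write_profile(TABLES / f"{name}_pgi_profile.txt", pos, vals)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for phase in ("in", "off"):
                pimg = reconstruct_pet(lors, PET_GRID, phase=phase)
                write_image(OUT / f"{name}_pet_{phase}.txt", pimg,
                            {"mode": f"pet-{phase}"})
                ppos, pvals = project_1d(pimg, axis="x", window=(-30, 30),
                                         normalize=True)
                write_profile(TABLES / f"{name}_pet_{phase}_profile.txt",
                              ppos, pvals)
    print(f"images under {OUT}/, profiles under {TABLES}/")


if __name__ == "__main__":
    main()
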