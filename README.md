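# hybridpgi

Hybrid Compton prompt-gamma + in-beam PET ion-range verification: a tested
analysis pipeline from list-mode gamma-hit streams to Bragg-peak and
fall-off estimates, with a seeded synthetic event generator standing in
for (unavailable) experimental beam data.

## The problem

Ion-beam therapy deposits most of its dose at the Bragg peak, but the peak
depth in tissue carries percent-level uncertainty, forcing conservative
margins.  Two in-vivo imaging handles exist: *prompt-gamma imaging* (PGI)
of the 0.6–6 MeV de-excitation gammas emitted as ions slow down, and
*in-beam PET* of 511 keV pairs from β⁺ activation products (⁹C, ¹²N, ¹³O,
¹⁰C, ¹¹C, ¹⁵O).  An array of four Compton imagers (one monolithic scatter
crystal + four absorber crystals each) on either side of the beam can do
both at once: scatter–absorber coincidences within one imager give Compton
cones for PGI; cross-side coincidences give PET lines of response, split
into in-spill and off-spill phases of the pulsed synchrotron cycle
(300 ms period, 45 ms spill).  Short-lived emitters are strongly enhanced
between spills, which makes the off-spill PET image narrow and clean.

This package is for medical-physics researchers who want the full chain —
event generation with pulsed-activation dynamics, coincidence selection,
Compton and PET reconstruction on the beam-axis plane, range estimators,
and statistics-vs-precision studies — as importable, tested code.

## The core methods

* **Compton cones**: cos θ = 1 − m_ec²(1/E_abs − 1/(E_sc+E_abs)); events
  accepted in a ±10 ns window with 0.6–6 MeV sum and ≥ 0.6 MeV in the
  absorber.  Images by (a) Gaussian-band cone backprojection (oracle) and
  (b) an analytical spherical-expansion inversion: each cone ring has
  Legendre spectrum P_l(cos θ), so a per-degree inverse filter
  (normalized by the ensemble mean of P_l², truncated at l_max = 40,
  apodized, floor-regularized) deconvolves the ring data; both routes
  agree on the source position to the pixel.
* **PET**: LORs from ±10 ns cross-side pairs with 0.9–1.1 MeV sum,
  intersected with the z = 0 plane, histogrammed, and corrected by a
  Monte-Carlo pair-sensitivity map.
* **Range metrics**: weighted ≥ 95%-of-maximum peak position, 50% contour
  fall-off, Gaussian peak fits, and erfc distal-edge fits.
* **Sensitivity**: disjoint-subset variance-vs-statistics scaling (the
  spread shrinks ≈ √10 ≈ 3 per tenfold statistics) and the all-pairs
  |Δx_max| permutation test whose ECDF gives the achievable precision at a
  chosen confidence (q90).
* **Activation dynamics**: closed-form spill-train recursion
  N⁺(k) = N⁻(k−1)e^(−λτ_s) + (R/λ)(1 − e^(−λτ_s)), N⁻(k) = N⁺(k)e^(−λτ_b),
  against which the Monte-Carlo decay sampler is validated.

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

```python
from hybridpgi import (ScenarioConfig, generate_dataset, SelectionConfig,
                       build_pgi_coincidences, build_pet_coincidences,
                       SpillClock, find_max_weighted95)
from hybridpgi.compton import backproject_cones
from hybridpgi.images import GridSpec
from hybridpgi.metrics import phantom_mask

cfg = ScenarioConfig(energy_label="55MeV", phantom_position=-60.0,
                     n_prompt=120_000, n_annihilation=60_000,
                     n_spills=40, seed=77)
hits, manifest = generate_dataset(cfg)
cones, report = build_pgi_coincidences(hits, SelectionConfig(), SpillClock())
print(report)
grid = GridSpec((-105, -15, -20, 20), 90, 40)   # 1 mm pixels
img = backproject_cones(cones, grid, ring_sigma=3.0)
x_max, err = find_max_weighted95(img, mask=phantom_mask(img, (-85, -35)))
print(f"Bragg-peak x = {x_max:.2f} +- {err:.2f} mm")
```

prints

```
{'candidates': 52990, 'accepted': 39137, 'rejected_energy_sum': 5825,
 'rejected_absorber_min': 8018, 'rejected_kinematics': 10,
 'unmatched_scatter': 117116}
Bragg-peak x = -57.36 +- 2.34 mm
```

i.e. 39 137 accepted Compton cones out of 52 990 scatter–absorber
candidates, and a weighted-95% peak estimate ~2.6 mm shallow of the true
−60 mm peak (the plateau skews the top-intensity blob; the estimator's
*spread*, which the sensitivity studies measure, is sub-mm at this
statistics).  A CLI wraps the same stages
(`hybridpgi generate|reconstruct|range|sensitivity|all`).

## Analysis scripts

Numbered drivers under `analysis/` rebuild the study end to end, writing
small tables and profiles under `results/` and large regenerable artifacts
(hit streams, image matrices) under `scratch/`: `01_simulate_campaign.py`
(six irradiations:
graphite at 0/−60/−120 mm, PE at +0/+1/+1.5 mm shifts),
`02_reconstruct_images.py` (selection + PGI/PET images and profiles),
`03_range_estimates.py` (peak/fall-off tables, cross-modality deviations,
recovered sub-mm shifts), `04_statistics_scaling.py` (box-plot spread vs
statistics), `05_permutation_sensitivity.py` (|Δx_max| ECDFs, q90 vs
statistics and vs detector resolution).

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

regenerates the 55 MeV-like graphite scenario from scratch, draws 100
disjoint subsets of 2000 and of 20000 accepted Compton events, estimates
the Bragg-peak position of each by backprojection + weighted-95%, and
writes the ratio of the two spreads (the per-tenfold-statistics
variance-reduction factor) as JSON.
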