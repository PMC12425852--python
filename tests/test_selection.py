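import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from hybridpgi.activation import SpillClock
from hybridpgi.selection import (SelectionConfig, build_pet_coincidences,
                                 build_pgi_coincidences, classify_spill_phase)

CLOCK = SpillClock()
MS = 1e6  # ns per ms


def _hit(event_id, imager, layer, x, y, z, e, t, crystal=0):
    return dict(event_id=event_id, imager=imager, layer=layer,
                crystal_index=crystal, x_mm=x, y_mm=y, z_mm=z,
                energy_keV=e, time_ns=t)


def _frame(rows):
    return pd.DataFrame(rows)


def pgi_pair(e_scatter, e_absorber, dt=2.0, imager="A", t0=1000.0):
    return _frame([
        _hit(0, imager, "S", 0.0, 0.0, 103.0, e_scatter, t0),
        _hit(0, imager, "A", 5.0, 0.0, 150.0, e_absorber, t0 + dt),
    ])


class TestSpillPhase:
    @pytest.mark.parametrize("t_ms,expected", [
        (10.0, "in"),      # within the 45 ms spill
        (100.0, "off"),    # within the 255 ms break
        (310.0, "in"),     # second period, 10 ms into the spill
        (44.999, "in"),
        (45.001, "off"),
    ])
    def test_phase_boundaries(self, t_ms, expected):
        assert classify_spill_phase(t_ms * MS, CLOCK) == expected


class TestPgiSelection:
    def test_valid_pair_accepted(self):
        cones, report = build_pgi_coincidences(pgi_pair(300.0, 700.0),
                                               SelectionConfig())
        assert report["accepted"] == 1
        assert len(cones) == 1

    def test_absorber_below_600kev_rejected(self):
        cones, report = build_pgi_coincidences(pgi_pair(300.0, 500.0),
                                               SelectionConfig())
        assert report["rejected_absorber_min"] == 1
        assert len(cones) == 0

    def test_sum_above_6mev_rejected(self):
        _, report = build_pgi_coincidences(pgi_pair(3000.0, 3500.0),
                                           SelectionConfig())
        assert report["rejected_energy_sum"] == 1

    def test_outside_10ns_window_rejected(self):
        _, report = build_pgi_coincidences(pgi_pair(300.0, 700.0, dt=15.0),
                                           SelectionConfig())
        assert report["accepted"] == 0
        assert report["unmatched_scatter"] == 1

    def test_window_is_closed_at_exactly_10ns(self):
        _, report = build_pgi_coincidences(pgi_pair(300.0, 700.0, dt=10.0),
                                           SelectionConfig())
        assert report["accepted"] == 1

    def test_low_absorber_invalid_pair_hits_absorber_cut_first(self):
        # E1=400, E2=100: cos(theta) ~ -3.1, unphysical, but the 600 keV
        # absorber threshold already removes it (the threshold guarantees
        # kinematic validity: cos >= 1 - 511/600 > -1 for in-window pairs)
        _, report = build_pgi_coincidences(pgi_pair(400.0, 100.0),
                                           SelectionConfig())
        assert report["rejected_absorber_min"] == 1
        assert report["rejected_kinematics"] == 0

    def test_kinematically_invalid_pair_counted_with_loose_windows(self):
        # with the absorber threshold relaxed the same unphysical pair is
        # rejected by kinematics: E1=550, E2=100 -> cos(theta) ~ -3.3
        cfg = SelectionConfig(pgi_absorber_min_kev=50.0)
        _, report = build_pgi_coincidences(pgi_pair(550.0, 100.0), cfg)
        assert report["rejected_kinematics"] == 1

    def test_cross_imager_pairs_never_formed(self):
        hits = _frame([
            _hit(0, "A", "S", 0, 0, 103, 300.0, 0.0),
            _hit(0, "B", "A", -60, 0, 150, 700.0, 1.0),
        ])
        cones, report = build_pgi_coincidences(hits, SelectionConfig())
        assert len(cones) == 0

    def test_earliest_absorber_wins_ambiguity(self):
        hits = _frame([
            _hit(0, "A", "S", 0, 0, 103, 300.0, 100.0),
            _hit(1, "A", "A", 5, 0, 150, 700.0, 101.0),
            _hit(2, "A", "A", -5, 0, 150, 900.0, 103.0),
        ])
        cones, report = build_pgi_coincidences(hits, SelectionConfig())
        assert len(cones) == 1
        assert cones["e_absorber"].iloc[0] == 700.0

    def test_counting_conservation(self, rng):
        # random hit soup: accepted + per-cause rejected = candidates
        n = 400
        hits = _frame([
            _hit(i, rng.choice(["A", "B", "C", "D"]),
                 rng.choice(["S", "A"]), 0.0, 0.0, 103.0,
                 rng.uniform(50, 4000), rng.uniform(0, 5000.0))
            for i in range(n)
        ])
        _, r = build_pgi_coincidences(hits, SelectionConfig())
        assert r["accepted"] + r["rejected_energy_sum"] \
            + r["rejected_absorber_min"] + r["rejected_kinematics"] \
            == r["candidates"]

    @given(st.floats(min_value=600, max_value=2000),
           st.floats(min_value=1, max_value=10))
    @settings(max_examples=25, deadline=None)
    def test_tightening_windows_never_gains_events(self, e_min, dt):
        hits = pd.concat([pgi_pair(300.0, 700.0),
                          pgi_pair(200.0, 900.0, t0=5000.0),
                          pgi_pair(100.0, 650.0, dt=8.0, t0=9000.0)],
                         ignore_index=True)
        loose = SelectionConfig()
        tight = SelectionConfig(dt_pgi_ns=dt, pgi_absorber_min_kev=e_min)
        _, rl = build_pgi_coincidences(hits, loose)
        _, rt = build_pgi_coincidences(hits, tight)
        assert rt["accepted"] <= rl["accepted"]

    def test_ideal_doublets_recovered_exactly_once(self, setup, rng):
        # no smearing, no background: every generated Compton doublet whose
        # exact energies pass the windows yields exactly one accepted cone
        from hybridpgi.generate import sample_prompt_gammas, transport_to_hits
        from hybridpgi.profiles import graphite_55mev_model
        from hybridpgi.transport import DetectorResponse

        em = sample_prompt_gammas(graphite_55mev_model(-60.0), 800, CLOCK,
                                  10, rng)
        hits, _ = transport_to_hits(em, setup, DetectorResponse(0.0, 0.0),
                                    "prompt", rng)
        cfg = SelectionConfig()
        by_event = hits.groupby("event_id")
        expected = 0
        for _, g in by_event:
            if set(g["layer"]) != {"S", "A"} or len(g) != 2:
                continue
            e1 = float(g[g["layer"] == "S"]["energy_keV"].iloc[0])
            e2 = float(g[g["layer"] == "A"]["energy_keV"].iloc[0])
            if e2 >= cfg.pgi_absorber_min_kev and \
                    cfg.pgi_sum_window_kev[0] <= e1 + e2 \
                    <= cfg.pgi_sum_window_kev[1]:
                expected += 1
        cones, report = build_pgi_coincidences(hits, cfg)
        assert report["accepted"] == expected
        assert len(cones) == expected


class TestPetSelection:
    def _pair(self, e1, e2, z2=-103.0, dt=2.0):
        return _frame([
            _hit(0, "A", "S", 0, 0, 103.0, e1, 0.0),
            _hit(1, "D", "S", 0, 0, z2, e2, dt),
        ])

    def test_compton_escape_pair_accepted(self):
        # 511 + 440 keV on opposite sides: sum 951 in [900, 1100]
        lors, r = build_pet_coincidences(self._pair(511.0, 440.0),
                                         SelectionConfig())
        assert r["accepted"] == 1
        assert np.sign(lors["z1"].iloc[0]) != np.sign(lors["z2"].iloc[0])

    def test_sum_1150_rejected(self):
        _, r = build_pet_coincidences(self._pair(511.0, 639.0),
                                      SelectionConfig())
        assert r["rejected_energy_sum"] == 1

    def test_same_side_pair_is_not_a_lor(self):
        _, r = build_pet_coincidences(self._pair(511.0, 511.0, z2=110.0),
                                      SelectionConfig())
        assert r["rejected_same_side"] == 1
        assert r["accepted"] == 0

    def test_counting_conservation(self, rng):
        n = 300
        hits = _frame([
            _hit(i, "A", "S", 0.0, 0.0, float(rng.choice([-103.0, 103.0])),
                 rng.uniform(300, 700), rng.uniform(0, 2000.0))
            for i in range(n)
        ])
        _, r = build_pet_coincidences(hits, SelectionConfig())
        assert r["accepted"] + r["rejected_energy_sum"] \
            + r["rejected_same_side"] == r["candidates"]

    def test_spill_phase_tag_uses_earlier_hit(self):
        hits = self._pair(511.0, 511.0)
        hits.loc[0, "time_ns"] = 45.0 * MS - 4.0  # just inside the spill
        hits.loc[1, "time_ns"] = 45.0 * MS + 4.0  # just after it ends
        lors, _ = build_pet_coincidences(hits, SelectionConfig())
        assert lors["spill_phase"].iloc[0] == "in"
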