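import numpy as np
import pandas as pd
import pytest
from scipy import integrate

from hybridpgi.activation import SpillClock
from hybridpgi.generate import (ScenarioConfig, generate_dataset,
                                sample_annihilations, sample_prompt_gammas,
                                transport_to_hits)
from hybridpgi.profiles import (DepthProfile, EmissionModel, ModelError,
                                default_isotopes, graphite_55mev_model,
                                pe_155mev_model)
from hybridpgi.transport import (DetectorResponse, klein_nishina_pdf,
                                 sample_klein_nishina, trace_annihilations,
                                 trace_prompt)

CLOCK = SpillClock()


def _point_model(x0: float = -80.0) -> EmissionModel:
    prof = DepthProfile(x_min=x0 - 10, x_max=x0 + 10, peak_position=x0,
                        peak_sigma=0.0)
    return EmissionModel(prof, default_isotopes(prof),
                         positron_range_sigma=0.0,
                         beam_sigma_transverse=0.0)


class TestPromptSampling:
    def test_point_profile_limit(self, rng):
        em = sample_prompt_gammas(_point_model(), 500, CLOCK, 5, rng)
        assert (em["x"] == -80.0).all()

    def test_bragg_gaussian_sample_mean(self, rng):
        prof = DepthProfile(x_min=-120, x_max=-40, peak_position=-80.0,
                            peak_sigma=5.0)
        model = EmissionModel(prof, default_isotopes(prof))
        em = sample_prompt_gammas(model, 100_000, CLOCK, 5, rng)
        # 3 sigma / sqrt(n) ~ 0.047 mm standard-error bound
        assert em["x"].mean() == pytest.approx(-80.0, abs=0.05)

    def test_times_within_spill_windows(self, rng):
        em = sample_prompt_gammas(_point_model(), 5000, CLOCK, 7, rng)
        assert CLOCK.in_spill(em["time_ns"].to_numpy()).all()
        assert em["time_ns"].max() <= 7 * CLOCK.period_ns

    def test_line_weights_must_sum_to_one(self):
        prof = DepthProfile(x_min=-10, x_max=10)
        with pytest.raises(ModelError):
            EmissionModel(prof, default_isotopes(prof),
                          prompt_lines=((511.0, 0.5), (1000.0, 0.6)))


class TestAnnihilationSampling:
    def test_point_production_zero_blur(self, rng):
        ann = sample_annihilations(_point_model(-100.0), CLOCK, 3, 300, rng)
        assert (ann["x"] == -100.0).all()

    def test_pair_directions_are_antiparallel_unit_vectors(self, rng):
        ann = sample_annihilations(_point_model(), CLOCK, 3, 1000, rng)
        d1 = ann[["dx", "dy", "dz"]].to_numpy()
        d2 = -d1  # the second photon flies exactly opposite by construction
        np.testing.assert_allclose(np.linalg.norm(d1, axis=1), 1.0,
                                   atol=1e-12)
        np.testing.assert_allclose(np.einsum("ij,ij->i", d1, d2), -1.0,
                                   atol=1e-12)

    def test_offspill_fraction_matches_recursion(self, rng):
        from hybridpgi.activation import expected_decays_per_phase
        prof = DepthProfile(x_min=-10, x_max=10, peak_position=0,
                            peak_sigma=2.0)
        iso = default_isotopes(prof, yields={"12N": 1.0})
        model = EmissionModel(prof, iso)
        n = 30_000
        ann = sample_annihilations(model, CLOCK, 30, n, rng)
        lam = np.log(2) / 0.010
        d_in, d_off = expected_decays_per_phase(1.0, lam, CLOCK, 30)
        frac_off = 1.0 - CLOCK.in_spill(ann["time_ns"].to_numpy()).mean()
        assert abs(frac_off * n - n * d_off / (d_in + d_off)) \
            < 3 * np.sqrt(n)


class TestKleinNishina:
    @pytest.mark.parametrize("e_kev", [511.0, 4440.0])
    def test_sample_mean_matches_quadrature(self, e_kev, rng):
        # independent oracle: direct numerical integration of the KN law
        k = e_kev / 511.0

        def kn(c):
            eps = 1.0 / (1.0 + k * (1.0 - c))
            return eps ** 2 * (eps + 1.0 / eps - (1.0 - c ** 2))

        norm, _ = integrate.quad(kn, -1, 1)
        mean, _ = integrate.quad(lambda c: c * kn(c), -1, 1)
        mean /= norm
        var, _ = integrate.quad(lambda c: (c - mean) ** 2 * kn(c), -1, 1)
        var /= norm
        n = 50_000
        c = sample_klein_nishina(e_kev, n, rng)
        assert abs(c.mean() - mean) < 3 * np.sqrt(var / n)

    def test_forward_peaking_grows_with_energy(self):
        c = np.linspace(-1, 1, 200)
        low = klein_nishina_pdf(c, 200.0)
        high = klein_nishina_pdf(c, 4440.0)
        assert (high[-1] / high[0]) > (low[-1] / low[0])


class TestTransport:
    def test_energy_conservation_exact_before_smearing(self, setup, rng):
        model = _point_model()
        em = sample_prompt_gammas(model, 4000, CLOCK, 3, rng)
        hits, counts = transport_to_hits(
            em, setup, DetectorResponse(0.0, 0.0), "prompt", rng)
        doublets = hits.groupby("event_id").filter(lambda g: len(g) == 2)
        sums = doublets.groupby("event_id")["energy_keV"].sum()
        lines = {e for e, _ in model.prompt_lines}
        for s in sums:
            assert min(abs(s - e) for e in lines) < 1e-9

    def test_aimed_annihilation_photon_full_energy_hit(self, setup, rng):
        # one pair aimed at imager A's scatter center, ideal response:
        # the first photon deposits exactly 511 keV on its entry ray
        target = setup.imagers["A"].scatter.center
        origin = np.array([[target[0], target[1], 0.0]])
        d = (target - origin[0])
        d = (d / np.linalg.norm(d))[None, :]
        hits, _ = trace_annihilations(origin, d, np.array([0.0]),
                                      np.array([0]), setup,
                                      DetectorResponse(0.0, 0.0), rng,
                                      efficiency=1.0)
        up = hits[hits["z_mm"] > 0]
        assert len(up) == 1
        assert up["energy_keV"].iloc[0] == pytest.approx(511.0)
        assert up["x_mm"].iloc[0] == pytest.approx(target[0], abs=1e-9)

    def test_position_smearing_width(self, setup, rng):
        target = setup.imagers["A"].scatter.center
        origin = np.tile([target[0], target[1], 0.0], (10_000, 1))
        d = np.tile((target - origin[0]) / np.linalg.norm(target - origin[0]),
                    (10_000, 1))
        hits, _ = trace_annihilations(origin, d, np.zeros(10_000),
                                      np.arange(10_000), setup,
                                      DetectorResponse(0.0, 1.0), rng,
                                      efficiency=1.0)
        up = hits[hits["z_mm"] > 0]
        # chord-depth variation only affects z; x is pure smearing
        assert up["x_mm"].std() == pytest.approx(1.0, abs=0.05)

    def test_missed_photons_are_counted(self, setup, rng):
        em = pd.DataFrame({"x": [0.0], "y": [0.0], "z": [0.0],
                           "energy_keV": [4440.0], "time_ns": [0.0]})
        # un-aimed single photon almost surely misses: counts must balance
        hits, counts = transport_to_hits(em, setup, DetectorResponse(),
                                         "prompt", rng, aim=False)
        assert counts["emitted"] == 1
        assert counts["missed_scatter"] + counts["scatter_only"] \
            + counts["doublets"] == 1


class TestGenerateDataset:
    CFG = dict(n_prompt=2000, n_annihilation=1000, n_spills=5)

    def test_same_seed_identical_files(self, tmp_path):
        for sub in ("a", "b"):
            cfg = ScenarioConfig(seed=7, **self.CFG)
            generate_dataset(cfg, out_prefix=str(tmp_path / sub))
        assert (tmp_path / "a_hits.csv").read_bytes() \
            == (tmp_path / "b_hits.csv").read_bytes()

    def test_shift_moves_truth_by_exactly_1mm(self):
        _, m0 = generate_dataset(ScenarioConfig(seed=1, **self.CFG))
        _, m1 = generate_dataset(ScenarioConfig(seed=1, phantom_shift=1.0,
                                                **self.CFG))
        assert m1["truth"]["prompt_peak_x_mm"] \
            - m0["truth"]["prompt_peak_x_mm"] == pytest.approx(1.0)

    def test_flash_component_by_species(self):
        _, mp = generate_dataset(ScenarioConfig(
            seed=1, species="p", energy_label="155MeV", **self.CFG))
        _, mhe = generate_dataset(ScenarioConfig(
            seed=1, species="He", energy_label="155MeV", **self.CFG))
        assert mp["truth"]["flash_amplitude"] == 0.0
        assert mhe["truth"]["flash_amplitude"] > 0.0

    def test_manifest_records_seed_and_counts(self):
        hits, man = generate_dataset(ScenarioConfig(seed=42, **self.CFG))
        assert man["seed"] == 42
        assert man["counts"]["prompt"]["emitted"] == self.CFG["n_prompt"]
        assert len(hits) > 0
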