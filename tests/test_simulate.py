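"""Synthetic generators and the Gaussian-noise robustness study."""
import numpy as np
import pytest

import pcctspr as p
from pcctspr import simulate as sim


class TestSyntheticTable:
    def test_three_pfm_fit_is_exact_by_construction(self, exact_table, realistic_table):
        assert p.fit_three_pfm(exact_table).max_rel_error < 1e-10
        assert p.fit_three_pfm(realistic_table).max_rel_error < 1e-10

    def test_two_pfm_exact_on_quadratic_friendly_rules(self, exact_table):
        assert p.fit_two_pfm(exact_table).max_rel_error < 1e-10

    def test_grid_round_trip(self, tmp_path, realistic_table):
        path = tmp_path / "t.csv"
        realistic_table.to_csv(path)
        back = p.load_attenuation_table(path)
        np.testing.assert_array_equal(back.Z, realistic_table.Z)
        np.testing.assert_array_equal(
            back.mu_over_rhoe_grid, realistic_table.mu_over_rhoe_grid
        )

    def test_total_decreases_with_energy(self, realistic_table):
        assert np.all(np.diff(realistic_table.mu_over_rhoe_grid, axis=0) < 0)


class TestToySpectrum:
    def test_zero_fluence_at_tube_voltage(self):
        spec = sim.make_toy_spectrum(kvp=150.0)
        assert spec(150.0) == pytest.approx(0.0, abs=1e-9)

    def test_window_weights_normalised(self, toy_spectrum):
        for win in p.DEFAULT_WINDOWS:
            assert p.window_weights(toy_spectrum, win).integral() == pytest.approx(1.0, abs=1e-6)

    def test_filtration_raises_mean_energy(self):
        soft = sim.make_toy_spectrum(filtration=0.5)
        hard = sim.make_toy_spectrum(filtration=3.0)
        for win in p.DEFAULT_WINDOWS:
            assert p.mean_energy(hard, win) > p.mean_energy(soft, win)

    def test_kvp_below_windows_rejected(self):
        spec = sim.make_toy_spectrum(kvp=100.0)
        with pytest.raises(ValueError, match="outside"):
            p.window_weights(spec, p.DEFAULT_WINDOWS[3])


class TestPhantom:
    def test_zero_noise_is_piecewise_constant_theory(self, seven_rods, realistic_table, toy_spectrum):
        images, rois = sim.make_phantom_images(seven_rods, realistic_table, toy_spectrum)
        for m, roi in zip(seven_rods, rois.values()):
            for k, win in enumerate(p.DEFAULT_WINDOWS):
                expected = p.spectrum_weighted_mu(realistic_table, m, toy_spectrum, win)
                np.testing.assert_allclose(images.stack[k][roi], expected, rtol=1e-12)

    def test_water_only_phantom_uniform_inside_holder(self, realistic_table, toy_spectrum):
        images, _ = sim.make_phantom_images(
            [p.WATER], realistic_table, toy_spectrum, rod_centers=[(0.0, 0.0)]
        )
        inside = images.stack[0] > 0
        assert np.unique(images.stack[0][inside]).size == 1

    def test_same_seed_reproducible(self, seven_rods, realistic_table, toy_spectrum):
        a, _ = sim.make_phantom_images(seven_rods, realistic_table, toy_spectrum,
                                       noise_sigma=0.06, seed=5)
        b, _ = sim.make_phantom_images(seven_rods, realistic_table, toy_spectrum,
                                       noise_sigma=0.06, seed=5)
        np.testing.assert_array_equal(a.stack, b.stack)

    def test_overlapping_rods_rejected(self, realistic_table, toy_spectrum, materials):
        with pytest.raises(ValueError, match="overlap"):
            sim.make_phantom_images(
                [materials["PMMA"], materials["Water"]],
                realistic_table, toy_spectrum,
                rod_centers=[(0.0, 0.0), (3.0, 0.0)],
            )

    def test_rod_outside_holder_rejected(self, realistic_table, toy_spectrum, materials):
        with pytest.raises(ValueError, match="holder"):
            sim.make_phantom_images(
                [materials["PMMA"]], realistic_table, toy_spectrum,
                rod_centers=[(14.0, 0.0)],
            )


class TestBraggGenerator:
    def test_peak_location_tracks_shift(self):
        a = sim.make_bragg_curve(shift_mm=0.0)
        b = sim.make_bragg_curve(shift_mm=7.0)
        da = a.depth_mm[np.argmax(a.signal)]
        db = b.depth_mm[np.argmax(b.signal)]
        assert da - db == pytest.approx(7.0, abs=0.2)


@pytest.fixture(scope="module")
def study_inputs(realistic_table, toy_spectrum, weighted_two_real, weighted_three_real,
                 mixture_curve, beam, water_ref, seven_rods):
    return dict(
        materials=seven_rods, table=realistic_table, spectrum=toy_spectrum,
        windows=p.DEFAULT_WINDOWS, two_model=weighted_two_real,
        three_model=weighted_three_real, curve=mixture_curve, beam=beam,
        water_ref=water_ref,
    )


class TestNoiseStudy:
    def test_zero_noise_degenerates_to_noiseless_exactly(self, study_inputs):
        cfg = sim.NoiseStudyConfig(sigma=0.0, n_replicates=16, seed=1)
        res = sim.run_noise_study(cfg, **{k: v for k, v in study_inputs.items() if k != "materials"},
                                  materials=study_inputs["materials"][:2])
        for (mat, meth), row in res.table.iterrows():
            for q in ("zeff", "rhoe", "ivalue", "spr"):
                assert row[f"{q}_std"] == 0.0
                assert row[f"{q}_mean"] == res.noiseless.loc[(mat, meth), q]

    def test_same_seed_identical_results(self, study_inputs):
        cfg = sim.NoiseStudyConfig(sigma=0.06, n_replicates=64, seed=9)
        kw = {k: v for k, v in study_inputs.items() if k != "materials"}
        r1 = sim.run_noise_study(cfg, materials=study_inputs["materials"][:2], **kw)
        r2 = sim.run_noise_study(cfg, materials=study_inputs["materials"][:2], **kw)
        assert r1.table.equals(r2.table)

    def test_std_scales_linearly_for_small_sigma(self, study_inputs):
        """First-order noise propagation: doubling sigma from 1% to 2%
        doubles the output spread (within 20%) for a mid-Z material."""
        kw = {k: v for k, v in study_inputs.items() if k != "materials"}
        mats = [m for m in study_inputs["materials"] if m.name == "BE-T-10"]
        stds = {}
        for sig in (0.01, 0.02):
            cfg = sim.NoiseStudyConfig(sigma=sig, n_replicates=1024, seed=3)
            res = sim.run_noise_study(cfg, materials=mats, **kw)
            stds[sig] = [res.std("BE-T-10", meth, q)
                         for meth in ("two-pfm", "three-pfm")
                         for q in ("zeff", "rhoe", "spr")]
        ratios = np.array(stds[0.02]) / np.array(stds[0.01])
        assert np.all(np.abs(ratios / 2.0 - 1.0) < 0.2)

    def test_failed_replicates_counted_not_propagated(self, study_inputs):
        cfg = sim.NoiseStudyConfig(sigma=0.2, n_replicates=128, seed=2)
        kw = {k: v for k, v in study_inputs.items() if k != "materials"}
        mats = [m for m in study_inputs["materials"] if m.name == "Graphite"]
        res = sim.run_noise_study(cfg, materials=mats, **kw)
        row = res.table.loc[("Graphite", "three-pfm")]
        assert row["n_failed"] >= 0
        assert np.isfinite(row["spr_mean"])

    def test_summary_mentions_conditions(self, study_inputs):
        cfg = sim.NoiseStudyConfig(sigma=0.06, n_replicates=8, seed=0)
        kw = {k: v for k, v in study_inputs.items() if k != "materials"}
        res = sim.run_noise_study(cfg, materials=study_inputs["materials"][:1], **kw)
        assert "sigma=0.060" in res.summary()
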