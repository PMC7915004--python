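"""Two- and three-PFM fitting and four-window inversion."""
import numpy as np
import pytest

import pcctspr as p
from pcctspr.pfm import Z_BRACKET

MONO = [40.0, 60.0, 80.0, 100.0]


def model_mu_two(weighted, Z, rhoe):
    return np.array([rhoe * weighted.A(k, np.array([Z]))[0] for k in range(4)])


def model_mu_three(weighted, Z, rhoe):
    return np.array([rhoe * weighted.response(k, np.array([Z]))[0] for k in range(4)])


class TestTwoPFMFit:
    def test_model_consistent_table_fits_exactly(self, two_exact):
        assert two_exact.max_rel_error < 1e-10

    def test_reconstruction_within_recorded_error(self, two_real, realistic_table):
        got = two_real.mu_over_rhoe(80.0, 13)
        ref = p.mu_over_rhoe(realistic_table, 80.0, 13)
        assert abs(got - ref) / ref <= two_real.max_rel_error * (1 + 1e-9)

    def test_errors_larger_at_low_energy(self, two_real):
        # photoelectric dominance at low E makes the quadratic-in-Z form
        # misfit worst there (error profile concentrated at low E)
        per_energy = np.max(np.abs(two_real.rel_err), axis=1)
        assert per_energy[0] > per_energy[-1]

    def test_serialisation_round_trip(self, tmp_path, two_real):
        path = tmp_path / "two.json"
        two_real.to_json(path)
        from pcctspr.pfm import TwoPFMResult

        back = TwoPFMResult.from_json(path)
        np.testing.assert_allclose(back.f_coefs, two_real.f_coefs)
        np.testing.assert_allclose(back.g_coefs, two_real.g_coefs)
        assert back.max_rel_error == two_real.max_rel_error

    def test_summary_reports_error(self, two_real):
        assert "reconstruction error" in two_real.summary()


class TestThreePFMFit:
    def test_power_law_table_fits_exactly(self, three_exact, three_real):
        assert three_exact.max_rel_error < 1e-10
        assert three_real.max_rel_error < 1e-10

    def test_exponent_surface_matches_generating_rule(self, three_real):
        # realistic generator uses Z^3.6 for the photoelectric channel
        assert three_real.exponent("pe", 60.0, 10.0) == pytest.approx(3.6, abs=1e-6)
        assert three_real.exponent("coh", 80.0, 10.0) == pytest.approx(1.5, abs=1e-6)

    def test_reconstruction_not_worse_than_two_pfm(self, two_real, three_real):
        assert three_real.max_rel_error < two_real.max_rel_error

    def test_serialisation_round_trip(self, tmp_path, three_real):
        path = tmp_path / "three.json"
        three_real.to_json(path)
        from pcctspr.pfm import ThreePFMResult

        back = ThreePFMResult.from_json(path)
        for ch in ("pe", "incoh", "coh"):
            np.testing.assert_allclose(back.coefs[ch], three_real.coefs[ch])


class TestWeighting:
    def test_delta_spectrum_reduces_to_monochromatic(self, two_real, three_real):
        # very narrow spectra centred on each window's analysis energy
        E = np.arange(30.0, 150.5, 0.05)
        windows = p.DEFAULT_WINDOWS
        centres = [50.0, 70.0, 90.0, 110.0]
        phi = sum(np.exp(-(((E - c) / 0.05) ** 2)) for c in centres)
        spec = p.SpectrumModel(E, phi)
        w2 = two_real.weighted(spec, windows)
        m2 = two_real.at_energies(centres)
        z = np.linspace(2, 29, 7)
        for k in range(4):
            np.testing.assert_allclose(w2.A(k, z), m2.A(k, z), rtol=2e-4)
        w3 = three_real.weighted(spec, windows)
        m3 = three_real.at_energies(centres)
        for k in range(4):
            np.testing.assert_allclose(w3.response(k, z), m3.response(k, z), rtol=2e-4)

    def test_flat_spectrum_equals_unweighted_mean(self, three_real):
        E = np.arange(30.0, 150.5, 1.0)
        spec = p.SpectrumModel(E, np.ones_like(E))
        w3 = three_real.weighted(spec, p.DEFAULT_WINDOWS)
        grid = np.linspace(40.0, 60.0, 201)
        z = np.array([10.0])
        oracle = np.mean([three_real.mu_over_rhoe(e, 10.0) for e in grid])
        assert w3.response(0, z)[0] == pytest.approx(oracle, rel=1e-4)

    def test_weighted_coefficients_match_trapezoid_oracle(self, two_real, toy_spectrum):
        w2 = two_real.weighted(toy_spectrum, p.DEFAULT_WINDOWS)
        grid = np.linspace(40.0, 60.0, 201)
        phi = toy_spectrum(grid)
        z0 = 13.0
        vals = np.array([two_real.mu_over_rhoe(e, z0) for e in grid])
        oracle = np.trapezoid(vals * phi, grid) / np.trapezoid(phi, grid)
        assert w2.A(0, np.array([z0]))[0] == pytest.approx(oracle, rel=1e-3)


class TestTwoPFMSolve:
    def test_model_consistent_round_trip_rhoe_cancels(self, mono_two_exact):
        for rhoe in (1e21, 3e23, 5e24):
            mu = model_mu_two(mono_two_exact, 10.0, rhoe)
            res = mono_two_exact.solve_zeff(mu)
            assert res.converged
            assert res.zeff == pytest.approx(10.0, abs=1e-8)
            assert res.rhoe == pytest.approx(rhoe, rel=1e-10)

    def test_scale_invariance(self, weighted_two_real):
        mu = model_mu_two(weighted_two_real, 12.0, 4e23)
        r1 = weighted_two_real.solve_zeff(mu)
        r2 = weighted_two_real.solve_zeff(5.0 * mu)
        assert r2.zeff == pytest.approx(r1.zeff, abs=1e-9)
        assert r2.rhoe == pytest.approx(5.0 * r1.rhoe, rel=1e-10)

    def test_water_zeff_between_7_and_8(self, weighted_two_real, realistic_table, toy_spectrum):
        mu = [
            p.spectrum_weighted_mu(realistic_table, p.WATER, toy_spectrum, w)
            for w in p.DEFAULT_WINDOWS
        ]
        res = weighted_two_real.solve_zeff(mu)
        assert 7.0 < res.zeff < 8.0

    def test_rhoe_literal_form_runs_but_is_not_exact(self, mono_two_exact):
        mu = model_mu_two(mono_two_exact, 10.0, 3e23)
        lsq = mono_two_exact.solve_rhoe(mu, 10.0, method="lsq")
        literal = mono_two_exact.solve_rhoe(mu, 10.0, method="literal")
        assert lsq == pytest.approx(3e23, rel=1e-10)
        assert literal > 0

    def test_invalid_mu_not_converged(self, mono_two_exact):
        res = mono_two_exact.solve_zeff([0.0, 0.1, 0.1, 0.1])
        assert not res.converged


class TestThreePFMSolve:
    def test_model_consistent_round_trip(self, mono_three_exact):
        mu = model_mu_three(mono_three_exact, 13.0, 7.8e23)
        res = mono_three_exact.solve_zeff(mu)
        assert res.converged
        assert res.zeff == pytest.approx(13.0, abs=1e-6)
        assert res.rhoe == pytest.approx(7.8e23, rel=1e-10)

    def test_residual_root_bracketed_by_dense_scan(self, mono_three_exact):
        # independent dense scan of the root condition around the answer
        mu = model_mu_three(mono_three_exact, 17.3, 2e23)
        res = mono_three_exact.solve_zeff(mu)
        cc = np.array([-mu[1], mu[0] - mu[2], mu[1] - mu[3], mu[2]])
        z = np.linspace(res.zeff - 0.5, res.zeff + 0.5, 1001)
        g = sum(cc[k] * mono_three_exact.response(k, z) for k in range(4))
        assert g[0] * g[-1] < 0  # sign change around the returned root

    def test_scale_invariance_and_linearity(self, weighted_three_real):
        mu = model_mu_three(weighted_three_real, 9.0, 3.3e23)
        r1 = weighted_three_real.solve_zeff(mu)
        r2 = weighted_three_real.solve_zeff(2.0 * mu)
        assert r2.zeff == pytest.approx(r1.zeff, abs=1e-9)
        assert r2.rhoe == pytest.approx(2.0 * r1.rhoe, rel=1e-10)

    def test_no_root_reports_diagnostics(self, mono_three_exact):
        # ascending mu across windows cannot come from any Z in range
        res = mono_three_exact.solve_zeff([0.1, 0.2, 0.4, 0.8])
        if not res.converged:
            assert "no sign change" in res.diagnostics["reason"]

    def test_batch_matches_scalar(self, weighted_three_real):
        zs = [4.0, 9.5, 21.0]
        mus = np.column_stack([model_mu_three(weighted_three_real, z, 3e23) for z in zs])
        zb, rb, vb = weighted_three_real.solve_batch(mus)
        for j, z in enumerate(zs):
            scalar = weighted_three_real.solve_zeff(mus[:, j])
            assert zb[j] == pytest.approx(scalar.zeff, abs=1e-9)
            assert rb[j] == pytest.approx(scalar.rhoe, rel=1e-12)


class TestOracleEquivalence:
    """Both solvers recover (Z, rhoe) on model-consistent input across the
    full fitted Z range and three decades of electron density."""

    def test_recovery_grid(self, weighted_two_real, weighted_three_real):
        zs = np.arange(2.0, 30.0)
        rhoes = [1e21, 1e22, 1e23, 1e24]
        for weighted, mk in (
            (weighted_two_real, model_mu_two),
            (weighted_three_real, model_mu_three),
        ):
            mus = np.column_stack(
                [mk(weighted, z, r) for z in zs for r in rhoes]
            )
            truth = [(z, r) for z in zs for r in rhoes]
            zb, rb, vb = weighted.solve_batch(mus)
            assert vb.all()
            for (z0, r0), zg, rg in zip(truth, zb, rb):
                assert zg == pytest.approx(z0, abs=1e-6)
                assert rg == pytest.approx(r0, rel=1e-6)

    def test_zeff_within_bracket(self, weighted_three_real):
        mu = model_mu_three(weighted_three_real, 29.0, 1e23)
        res = weighted_three_real.solve_zeff(mu)
        assert Z_BRACKET[0] <= res.zeff <= Z_BRACKET[1]
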