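"""Release kinetics, the 1D diffusion solver and its oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import erfc

from angioscaffold.gf_transport import (
    RELEASE_CASES,
    ConcentrationField,
    DiffusionParams,
    FitError,
    ReleaseCase,
    ReleaseProfile,
    fit_deff,
    mass_balance_error,
    release_profile_from_cumulative,
    rescale_release,
    sample_concentration,
    solve_diffusion_1d,
    synth_release_curve,
)


def constant_boundary(conc: float, t_end: float = 200.0) -> ReleaseProfile:
    return ReleaseProfile(
        np.array([0.0, t_end]), np.array([0.0, 0.0]), np.array([conc, conc]), 0.0
    )


class TestSynthReleaseCurve:
    def test_full_burst_releases_everything_at_t0(self):
        p = synth_release_curve(dose_ng=200.0, burst_fraction=1.0)
        assert np.allclose(p.cumulative_ng, 200.0)

    def test_asymptote_equals_dose(self):
        p = synth_release_curve(dose_ng=200.0, rate_per_h=0.01, duration_h=3000.0)
        assert p.cumulative_ng[-1] == pytest.approx(200.0, rel=1e-6)

    @settings(max_examples=60, deadline=None)
    @given(
        dose=st.floats(1.0, 1000.0),
        burst=st.floats(0.0, 1.0),
        rate=st.floats(0.004, 0.2),
    )
    def test_cumulative_monotone_nondecreasing(self, dose, burst, rate):
        p = synth_release_curve(dose_ng=dose, burst_fraction=burst, rate_per_h=rate)
        assert np.all(np.diff(p.cumulative_ng) >= -1e-9 * dose)
        assert np.all(p.boundary_conc_ng_per_ml >= 0.0)

    def test_underreleasing_parameters_rejected(self):
        with pytest.raises(ValueError, match="unreleased"):
            synth_release_curve(rate_per_h=0.001, burst_fraction=0.0, duration_h=100.0)


class TestDiffusionSolver:
    def test_zero_boundary_gives_zero_field(self):
        f = solve_diffusion_1d(constant_boundary(0.0), DiffusionParams(), t_end_h=50.0)
        assert np.all(f.conc == 0.0)

    def test_matches_erfc_before_sink_is_felt(self):
        # early-time semi-infinite solution: C = C0 erfc((H-y)/(2 sqrt(D t)))
        params = DiffusionParams(d_eff_um2_per_s=50.0, n_nodes=200, dt_s=30.0)
        f = solve_diffusion_1d(constant_boundary(100.0), params, t_end_h=3.0)
        for t in (1.0, 2.0, 3.0):
            y_um = f.y_mm * 1000.0
            analytic = 100.0 * erfc((4000.0 - y_um) / (2.0 * np.sqrt(50.0 * t * 3600.0)))
            assert np.max(np.abs(f.profile_at(t) - analytic)) <= 0.02 * 100.0

    def test_steady_state_profile_is_linear(self):
        params = DiffusionParams(d_eff_um2_per_s=100.0, n_nodes=60, dt_s=600.0)
        f = solve_diffusion_1d(constant_boundary(40.0, t_end=600.0), params, t_end_h=600.0)
        prof = f.profile_at(600.0)
        linear = 40.0 * f.y_mm / f.y_mm[-1]
        assert np.max(np.abs(prof - linear)) <= 0.01 * 40.0

    def test_mass_balance_closes(self):
        f = solve_diffusion_1d(synth_release_curve(), DiffusionParams(), t_end_h=1008.0)
        assert mass_balance_error(f) <= 0.01

    def test_solution_nonnegative(self):
        f = solve_diffusion_1d(synth_release_curve(), DiffusionParams(), t_end_h=500.0)
        assert np.all(f.conc >= 0.0)

    def test_explicit_scheme_agrees_with_implicit(self):
        release = constant_boundary(10.0)
        pi = DiffusionParams(n_nodes=80, dt_s=60.0)
        pe = DiffusionParams(n_nodes=80, dt_s=10.0)
        fi = solve_diffusion_1d(release, pi, t_end_h=24.0)
        fe = solve_diffusion_1d(release, pe, scheme="explicit", t_end_h=24.0)
        assert np.max(np.abs(fi.profile_at(24.0) - fe.profile_at(24.0))) <= 0.1

    def test_explicit_scheme_enforces_stability_bound(self):
        with pytest.raises(ValueError, match="unstable"):
            solve_diffusion_1d(
                constant_boundary(1.0),
                DiffusionParams(n_nodes=400, dt_s=600.0),
                scheme="explicit",
                t_end_h=1.0,
            )

    def test_refinement_changes_little(self):
        release = synth_release_curve(duration_h=200.0, rate_per_h=0.05)
        coarse = solve_diffusion_1d(release, DiffusionParams(n_nodes=80, dt_s=600.0), t_end_h=200.0)
        fine = solve_diffusion_1d(release, DiffusionParams(n_nodes=160, dt_s=300.0), t_end_h=200.0)
        t = 100.0
        prof_f = np.interp(coarse.y_mm, fine.y_mm, fine.profile_at(t))
        scale = np.max(np.abs(fine.conc))
        assert np.max(np.abs(coarse.profile_at(t) - prof_f)) <= 0.01 * scale


class TestReleaseCases:
    def test_case_a_is_identity(self):
        p = synth_release_curve()
        q = rescale_release(p, RELEASE_CASES["A"])
        assert np.array_equal(p.times_h, q.times_h)
        assert np.array_equal(p.boundary_conc_ng_per_ml, q.boundary_conc_ng_per_ml)

    @pytest.mark.parametrize("label", list("ABCDEF"))
    def test_delivered_dose_conserved(self, label):
        p = synth_release_curve(dose_ng=200.0)
        q = rescale_release(p, RELEASE_CASES[label])
        assert abs(q.delivered_dose_ng - 200.0) <= 0.001 * 200.0

    def test_case_d_triples_time_to_90_percent(self):
        p = synth_release_curve(dose_ng=200.0)
        q = rescale_release(p, RELEASE_CASES["D"])
        t90_a = np.interp(180.0, p.cumulative_ng, p.times_h)
        t90_d = np.interp(180.0, q.cumulative_ng, q.times_h)
        assert t90_d / t90_a == pytest.approx(3.0, rel=1e-6)

    def test_field_rescale_stretches_and_corrects(self):
        f = ConcentrationField(
            np.linspace(0, 4, 5), np.array([0.0, 10.0]), np.ones((2, 5)) * 6.0
        )
        g = rescale_release(f, RELEASE_CASES["D"])
        assert g.times_h[-1] == 30.0
        assert np.allclose(g.conc, 2.0)

    def test_unknown_case_label(self):
        with pytest.raises(ValueError, match="unknown release case"):
            ReleaseCase.from_label("Z")


class TestSampling:
    def make_field(self):
        y = np.array([0.0, 1.0, 2.0])
        t = np.array([0.0, 10.0])
        conc = np.array([[0.0, 2.0, 4.0], [0.0, 4.0, 8.0]])
        return ConcentrationField(y, t, conc)

    def test_boundary_and_host_values(self):
        f = self.make_field()
        assert sample_concentration(f, 2.0, 0.0) == 4.0
        assert sample_concentration(f, 0.0, 7.3) == 0.0

    def test_midpoint_is_arithmetic_mean(self):
        f = self.make_field()
        assert sample_concentration(f, 1.5, 0.0) == pytest.approx(3.0)
        assert sample_concentration(f, 1.0, 5.0) == pytest.approx(3.0)

    def test_out_of_domain_rejected(self):
        f = self.make_field()
        with pytest.raises(ValueError):
            sample_concentration(f, 3.0, 0.0)
        with pytest.raises(ValueError):
            sample_concentration(f, 1.0, 99.0)


class TestDeffFit:
    def make_observation(self, d_true=50.0, noise=0.0, seed=None):
        release = synth_release_curve(rate_per_h=0.05, duration_h=120.0)
        params = DiffusionParams(d_eff_um2_per_s=d_true, n_nodes=60, dt_s=600.0)
        obs = solve_diffusion_1d(release, params, t_end_h=120.0, output_dt_h=12.0)
        conc = obs.conc
        if noise:
            rng = np.random.default_rng(seed)
            conc = conc * (1.0 + noise * rng.standard_normal(conc.shape))
        return release, ConcentrationField(obs.y_mm, obs.times_h, conc)

    def test_noise_free_recovery_within_one_percent(self):
        release, obs = self.make_observation(d_true=50.0)
        best, _ = fit_deff(release, obs, params_template=DiffusionParams(n_nodes=60, dt_s=600.0))
        assert best.d_eff_um2_per_s == pytest.approx(50.0, rel=0.01)

    def test_noisy_recovery_within_ten_percent(self):
        release = None
        errors = []
        for seed in range(20):
            release, obs = self.make_observation(d_true=50.0, noise=0.05, seed=seed)
            best, _ = fit_deff(
                release, obs, params_template=DiffusionParams(n_nodes=60, dt_s=600.0)
            )
            errors.append(abs(best.d_eff_um2_per_s / 50.0 - 1.0))
        assert max(errors) <= 0.10

    def test_zero_observation_is_degenerate(self):
        release, obs = self.make_observation()
        flat = ConcentrationField(obs.y_mm, obs.times_h, np.zeros_like(obs.conc))
        with pytest.raises(FitError, match="degenerate"):
            fit_deff(release, flat)


def test_profile_from_cumulative_series():
    times = np.linspace(0.0, 300.0, 61)
    cumulative = 150.0 * (1.0 - np.exp(-0.02 * times))
    p = release_profile_from_cumulative(times, cumulative)
    assert p.total_dose_ng == pytest.approx(cumulative[-1])
    assert np.all(p.boundary_conc_ng_per_ml >= 0.0)
    # layer cannot hold more than everything released so far
    assert np.all(p.boundary_conc_ng_per_ml * p.layer_volume_ml <= cumulative + 1e-9)
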