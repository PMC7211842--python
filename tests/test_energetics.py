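"""Work bookkeeping and free-energy estimators."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from fimpull.constants import PN_NM_PER_KCAL_MOL, kbt
from fimpull.energetics import (
    ensemble_profile,
    FreeEnergyProfile,
    fit_smd_tail,
    jarzynski_estimate,
    mean_work_estimate,
    rip_work,
    smd_work_profile,
    trace_transition_works,
    transition_unfolding_work,
    work_distribution_summary,
)
from fimpull.polymer import FJCParams, WLCParams, fjc_force, wlc_force
from fimpull.segmentation import AnalysisError, BranchSegment, segment_trace
from fimpull.polymer import FitResult
from fimpull.synthetic import SMDSpec, generate_smd_trace
from fimpull.trace_io import Trace


def branch(P, L, end_x, start_x=0.0):
    fit = FitResult(WLCParams(P, L, 300.0), 0.0, 100, True)
    return BranchSegment(start_extension=start_x, end_extension=end_x, fit=fit)


class TestRipWork:
    def test_trapezoid_arithmetic(self):
        assert rip_work(300.0, 100.0, 10.0, 20.0) == pytest.approx(2000.0)

    def test_zero_forces_zero_work(self):
        assert rip_work(0.0, 0.0, 1.0, 2.0) == 0.0

    def test_symmetric_in_forces(self):
        assert rip_work(310.0, 95.0, 5.0, 17.0) == rip_work(95.0, 310.0, 5.0, 17.0)

    def test_degenerate_interval_rejected(self):
        with pytest.raises(ValueError):
            rip_work(10.0, 5.0, 3.0, 3.0)


class TestTransitionWork:
    def test_identity_and_quadrature_oracle(self):
        b1 = branch(0.4, 100.0, end_x=90.0)
        b2 = branch(0.4, 134.0, end_x=120.0, start_x=100.0)
        x1, x2 = 90.0, 100.0
        tw = transition_unfolding_work(b1, b2, x1, x2)
        # exact identity
        assert tw.w_unfold == tw.w_rip - tw.dg_s
        # independent quadrature of the same formula
        f1 = wlc_force(x1, b1.fit.params)
        f2 = wlc_force(x2, b2.fit.params)
        w_rip_ref = 0.5 * (f1 + f2) * (x2 - x1)
        dg_ref = (
            quad(lambda x: wlc_force(x, b2.fit.params), 0, x2, limit=200)[0]
            - quad(lambda x: wlc_force(x, b1.fit.params), 0, x1, limit=200)[0]
        )
        assert tw.w_unfold == pytest.approx(w_rip_ref - dg_ref, rel=1e-6)

    def test_no_transition_gives_zero_work(self):
        b1 = branch(0.4, 100.0, end_x=90.0)
        tw = transition_unfolding_work(b1, b1, 90.0, 90.0)
        assert tw.w_unfold == 0.0

    def test_unit_conversion_consistent(self):
        b1 = branch(0.4, 100.0, end_x=90.0)
        b2 = branch(0.4, 134.0, end_x=120.0, start_x=100.0)
        tw = transition_unfolding_work(b1, b2, 90.0, 100.0)
        assert tw.w_unfold_kcal_mol == pytest.approx(tw.w_unfold / PN_NM_PER_KCAL_MOL, rel=1e-12)

    def test_unconverged_fit_rejected(self):
        good = branch(0.4, 100.0, end_x=90.0)
        bad = BranchSegment(0.0, 90.0, FitResult(WLCParams(0.4, 100.0, 300.0), 0.0, 100, False))
        with pytest.raises(AnalysisError):
            transition_unfolding_work(bad, good, 90.0, 100.0)

    def test_all_transitions_satisfy_identity(self, noisy_afm):
        trace, _ = noisy_afm
        seg = segment_trace(trace)
        for tw in trace_transition_works(seg):
            assert tw.w_unfold == tw.w_rip - tw.dg_s


class TestSMDWorkProfile:
    fjc = FJCParams(0.8, 40.0, 1.5e4, 300.0)

    def _trace(self, x, f):
        return Trace("smd", np.arange(len(x), dtype=float), x, f)

    def test_pure_baseline_gives_zero_profile(self):
        x = np.linspace(0.0, 38.0, 2000)
        prof = smd_work_profile(self._trace(x, np.asarray(fjc_force(x, self.fjc))), self.fjc)
        assert np.max(np.abs(prof.work)) < 1.0  # kcal/mol, integration tolerance

    def test_constant_excess_force_gives_linear_profile(self):
        x = np.linspace(0.0, 38.0, 4000)
        f = np.asarray(fjc_force(x, self.fjc)) + 100.0
        prof = smd_work_profile(self._trace(x, f), self.fjc)
        expected = 100.0 * prof.extension / PN_NM_PER_KCAL_MOL
        assert np.allclose(prof.work, expected, atol=0.5)
        assert prof.final_work == pytest.approx(100.0 * 38.0 / PN_NM_PER_KCAL_MOL, rel=0.01)

    def test_injected_rip_work_recovered(self, clean_smd):
        trace, truth = clean_smd
        prof = smd_work_profile(trace, truth.fjc_params)
        assert prof.final_work == pytest.approx(
            truth.total_work / PN_NM_PER_KCAL_MOL, rel=0.02
        )

    def test_time_resampling_invariance(self, clean_smd):
        trace, truth = clean_smd
        prof = smd_work_profile(trace, truth.fjc_params)
        half = Trace("smd", trace.time[::2], trace.extension[::2], trace.force[::2])
        prof2 = smd_work_profile(half, truth.fjc_params)
        n = min(len(prof.work), len(prof2.work))
        assert np.allclose(prof.work[:n], prof2.work[:n], atol=2.0)

    def test_flat_trace_rejected(self):
        with pytest.raises(ValueError, match="extension"):
            smd_work_profile(self._trace(np.full(10, 0.01), np.zeros(10)), self.fjc)


class TestFitSMDTail:
    def test_clean_tail_recovery(self, clean_smd):
        trace, truth = clean_smd
        fjc = fit_smd_tail(trace)
        assert fjc.kuhn_length == pytest.approx(truth.fjc_params.kuhn_length, rel=0.02)
        assert fjc.contour_length == pytest.approx(truth.fjc_params.contour_length, rel=0.02)

    def test_margin_stability(self, clean_smd):
        trace, _ = clean_smd
        a = fit_smd_tail(trace, margin=2.0)
        b = fit_smd_tail(trace, margin=4.0)
        assert a.contour_length == pytest.approx(b.contour_length, rel=0.01)
        assert a.kuhn_length == pytest.approx(b.kuhn_length, rel=0.01)

    def test_no_drop_is_analysis_error(self):
        spec = SMDSpec(seed=1, rip_works=(), rip_centers=(), rip_widths=(),
                       force_noise_sd=0.0, extension_jitter_sd=0.0)
        trace, _ = generate_smd_trace(spec)
        with pytest.raises(AnalysisError, match="drop"):
            fit_smd_tail(trace)


class TestEstimators:
    def test_degenerate_sample(self):
        mean, sd, se = mean_work_estimate([10.0, 10.0, 10.0])
        assert (mean, sd, se) == (10.0, 0.0, 0.0)
        assert jarzynski_estimate([10.0, 10.0, 10.0]) == pytest.approx(10.0, rel=1e-12)

    def test_textbook_sample(self):
        mean, sd, se = mean_work_estimate([1.0, 2.0, 3.0])
        assert mean == pytest.approx(2.0)
        assert sd == pytest.approx(1.0)
        assert se == pytest.approx(1.0 / np.sqrt(3.0))

    def test_matches_streaming_oracle(self):
        rng = np.random.default_rng(3)
        w = rng.normal(500.0, 40.0, 10_000)
        mean, sd, _ = mean_work_estimate(w)
        # Welford's streaming algorithm as an independent path
        m, m2, n = 0.0, 0.0, 0
        for v in w:
            n += 1
            d = v - m
            m += d / n
            m2 += d * (v - m)
        assert mean == pytest.approx(m, rel=1e-10)
        assert sd == pytest.approx(np.sqrt(m2 / (n - 1)), rel=1e-10)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.0, 2000.0), min_size=1, max_size=50))
    def test_jarzynski_never_exceeds_mean(self, works):
        assert jarzynski_estimate(works) <= mean_work_estimate(works)[0] + 1e-9

    def test_gaussian_closed_form(self):
        # for W ~ N(mu, sigma^2): dF = mu - sigma^2 / (2 kBT)
        rng = np.random.default_rng(4)
        kbt_kcal = kbt(300.0) / PN_NM_PER_KCAL_MOL
        mu, sigma = 100.0, 1.2
        w = rng.normal(mu, sigma, 10_000)
        expected = mu - sigma**2 / (2 * kbt_kcal)
        assert jarzynski_estimate(w) == pytest.approx(expected, abs=0.2)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mean_work_estimate([])
        with pytest.raises(ValueError):
            jarzynski_estimate([])

    def test_summary_consistency(self):
        s = work_distribution_summary([10.0, 12.0, 14.0])
        assert s.mean_work_estimate == s.mean
        assert s.jarzynski_estimate <= s.mean


class TestEnsembleProfile:
    def _profile(self, scale):
        x = np.linspace(0.0, 30.0, 100)
        return FreeEnergyProfile(x, scale * x)

    def test_identical_profiles_have_zero_sd(self):
        ens = ensemble_profile([self._profile(2.0), self._profile(2.0)])
        assert np.allclose(ens.sd, 0.0)
        assert np.allclose(ens.work, 2.0 * ens.extension)

    def test_opposite_profiles_average_to_zero(self):
        ens = ensemble_profile([self._profile(1.5), self._profile(-1.5)])
        assert np.allclose(ens.work, 0.0, atol=1e-9)

    def test_pointwise_spread_recovered(self):
        rng = np.random.default_rng(5)
        slopes = rng.normal(2.0, 0.3, 12)
        ens = ensemble_profile([self._profile(s) for s in slopes])
        i = len(ens.extension) // 2
        x_mid = ens.extension[i]
        assert ens.sd[i] == pytest.approx(np.std(slopes, ddof=1) * x_mid, rel=1e-6)

    def test_disjoint_ranges_rejected(self):
        a = FreeEnergyProfile(np.linspace(0, 10, 20), np.zeros(20))
        b = FreeEnergyProfile(np.linspace(20, 30, 20), np.zeros(20))
        with pytest.raises(ValueError, match="disjoint"):
            ensemble_profile([a, b])
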