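"""Analyzer tests: downsampling, origin, extrema, branch fits, acceptance."""

import dataclasses

import numpy as np
import pytest

from fimpull.polymer import WLCParams, wlc_force
from fimpull.segmentation import (
    AnalysisError,
    AnalyzerConfig,
    detect_extrema,
    downsample,
    locate_origin,
    reconstruct_piecewise,
    segment_trace,
)
from fimpull.synthetic import (
    DEFECT_EXPECTED_REASON,
    SyntheticSpec,
    generate_afm_trace,
)
from fimpull.trace_io import Trace


def flat_trace(force, x0=0.0, x1=100.0, n=1000):
    x = np.linspace(x0, x1, n)
    return Trace("afm", np.arange(n, dtype=float), x, np.full(n, float(force)))


class TestDownsample:
    def test_constant_force_stays_constant(self):
        ds = downsample(flat_trace(42.0), 1.0)
        assert np.allclose(ds.force, 42.0)
        assert 95 <= len(ds) <= 105  # ~range/width bins

    def test_width_larger_than_range_gives_single_point(self):
        tr = flat_trace(7.0, 0.0, 5.0)
        ds = downsample(tr, 50.0)
        assert len(ds) == 1
        assert ds.extension[0] == pytest.approx(tr.extension.mean())
        assert ds.force[0] == pytest.approx(7.0)

    def test_noise_suppression_follows_bin_averaging(self):
        # 50 raw points per 1-nm bin with sigma=30 noise: binned values track
        # the clean ramp within the CLT scale at 99% of bins
        rng = np.random.default_rng(0)
        n = 10_000
        x = np.linspace(0.0, 200.0, n)
        clean = 2.0 * x
        tr = Trace("afm", np.arange(n, dtype=float), x, clean + rng.normal(0, 30, n))
        ds = downsample(tr, 1.0)
        resid = np.abs(ds.force - 2.0 * ds.extension)
        assert np.mean(resid < 3 * 30 / np.sqrt(50)) > 0.99

    def test_empty_width_rejected(self):
        with pytest.raises(ValueError):
            downsample(flat_trace(1.0), 0.0)


class TestLocateOrigin:
    def test_linear_crossing(self):
        n = 500
        x = np.linspace(0.0, 20.0, n)
        tr = Trace("afm", np.arange(n, dtype=float), x, x - 5.0)
        assert locate_origin(tr) == pytest.approx(5.0, abs=0.05)

    def test_all_positive_force_is_no_contact(self):
        with pytest.raises(AnalysisError, match="contact"):
            locate_origin(flat_trace(10.0))

    def test_origin_matches_generator_offset(self, noisy_afm, default_config):
        trace, truth = noisy_afm
        ds = downsample(trace, default_config.downsample_width)
        assert locate_origin(ds) == pytest.approx(
            truth.origin_offset, abs=default_config.downsample_width
        )


class TestDetectExtrema:
    def _sawtooth(self, peaks, n_per=400, rise=30.0):
        # idealized sawtooth in extension with given peak forces, flat tail
        xs, fs = [], []
        x0 = 0.0
        for p in peaks:
            span = p / rise
            xs.append(np.linspace(x0, x0 + span, n_per))
            fs.append(np.linspace(0.0, p, n_per))
            x0 += span + 0.5
        xs.append(np.linspace(x0, x0 + 40.0, n_per))
        fs.append(np.zeros(n_per))
        x = np.concatenate(xs)
        return Trace("afm", np.arange(len(x), dtype=float), x, np.concatenate(fs))

    def test_two_branch_sawtooth(self, default_config):
        ds = downsample(self._sawtooth([200.0, 400.0]), 1.0)
        ext = detect_extrema(ds, default_config)
        maxima = [e for e in ext if e.kind == "maximum"]
        assert len(maxima) == 2
        assert maxima[0].force == pytest.approx(200.0, abs=20.0)
        assert maxima[1].force == pytest.approx(400.0, abs=20.0)

    def test_monotone_ramp_has_no_transitions(self, default_config):
        n = 2000
        x = np.linspace(0.0, 100.0, n)
        tr = Trace("afm", np.arange(n, dtype=float), x, 3.0 * x)
        with pytest.raises(AnalysisError, match="transition"):
            detect_extrema(downsample(tr, 1.0), default_config)

    def test_all_rips_found_on_noisy_synthetic(self, noisy_afm, default_config):
        trace, truth = noisy_afm
        seg = segment_trace(trace, default_config)
        # one transition per unfolding event plus the detachment
        assert len(seg.transitions) == len(truth.events) + 1
        for tr, ev in zip(seg.transitions[:-1], truth.events):
            assert tr.x1 == pytest.approx(ev.x1, abs=default_config.downsample_width)


class TestSegmentation:
    def test_noise_free_branch_recovery(self, clean_afm, default_config):
        trace, truth = clean_afm
        seg = segment_trace(trace, default_config)
        assert seg.report.accepted
        # fits run on 1-nm-binned points, so a small convexity (Jensen) bias
        # relative to the point-wise parameters is expected
        for br, p_true in zip(seg.branches, truth.branch_params):
            assert br.fit.converged
            assert br.fit.params.persistence_length == pytest.approx(
                p_true.persistence_length, rel=0.05
            )
            assert br.fit.params.contour_length == pytest.approx(
                p_true.contour_length, rel=0.02
            )
        for tr, ev in zip(seg.transitions[:-1], truth.events):
            assert tr.peak_force == pytest.approx(ev.force, abs=1.0)
            assert tr.contour_increment == pytest.approx(ev.increment, abs=0.5)

    def test_determinism(self, noisy_afm, default_config):
        trace, _ = noisy_afm
        a = segment_trace(trace, default_config)
        b = segment_trace(trace, default_config)
        assert a.report == b.report
        assert [t.x1 for t in a.transitions] == [t.x1 for t in b.transitions]

    def test_raising_rmse_threshold_never_rejects_accepted(self, noisy_afm):
        trace, _ = noisy_afm
        cfg = AnalyzerConfig()
        accepted = segment_trace(trace, cfg).report.accepted
        looser = dataclasses.replace(cfg, rmse_max=cfg.rmse_max * 10)
        assert segment_trace(trace, looser).report.accepted >= accepted

    def test_report_records_every_criterion(self, noisy_afm, default_config):
        trace, _ = noisy_afm
        report = segment_trace(trace, default_config).report
        ids = [o.criterion for o in report.outcomes]
        for cid in ("tail_length", "tail_slope", "maxima_count", "i91_count",
                    "fimg_count", "detachment_tallest", "rmse",
                    "persistence_length", "i91_increment", "fimg_increment"):
            assert cid in ids
        assert report.accepted == all(o.passed for o in report.outcomes)


class TestDefectSuite:
    @pytest.mark.parametrize("kind", sorted(DEFECT_EXPECTED_REASON))
    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_defect_rejected_with_intended_reason(self, kind, seed):
        # probes are noise-free so each violates exactly one criterion
        trace, _ = generate_afm_trace(SyntheticSpec(defect=kind, seed=seed, noise_sd=0.0))
        seg = segment_trace(trace)
        assert not seg.report.accepted
        assert seg.report.rejection_reason == DEFECT_EXPECTED_REASON[kind]


class TestReconstruction:
    def test_endpoints_match_fitted_curves(self, clean_afm, default_config):
        trace, _ = clean_afm
        seg = segment_trace(trace, default_config)
        x, f = reconstruct_piecewise(seg)
        assert np.all(np.diff(x) >= 0)
        for br, tr in zip(seg.branches, seg.transitions):
            expected = wlc_force(
                min(tr.x1, br.fit.params.contour_length * (1 - 1e-9)), br.fit.params
            )
            i = np.argmin(np.abs(x - tr.x1))
            assert f[i] == pytest.approx(expected, rel=1e-6)

    def test_area_matches_quasi_static_work(self, clean_afm, default_config):
        trace, truth = clean_afm
        seg = segment_trace(trace, default_config)
        x, f = reconstruct_piecewise(seg, n_per_branch=3000)
        # up to the detachment peak: the quasi-static work of the pull
        keep = x <= seg.transitions[-1].x1
        area = np.trapezoid(f[keep], x[keep])
        true_area = (
            sum(e.w_rip for e in truth.events)
            + sum(
                np.trapezoid(
                    wlc_force(np.linspace(a, min(b, p.contour_length * (1 - 1e-9)), 3000), p),
                    np.linspace(a, min(b, p.contour_length * (1 - 1e-9)), 3000),
                )
                for p, a, b in zip(
                    truth.branch_params,
                    [0.0] + [e.x2 for e in truth.events],
                    [e.x1 for e in truth.events] + [truth.detachment_extension],
                )
            )
        )
        assert area == pytest.approx(true_area, rel=0.01)

    def test_rejected_trace_cannot_be_reconstructed(self):
        trace, _ = generate_afm_trace(
            SyntheticSpec(defect="short_tail", seed=1, noise_sd=0.0)
        )
        seg = segment_trace(trace)
        with pytest.raises(ValueError, match="accepted"):
            reconstruct_piecewise(seg)


class TestConfig:
    def test_yaml_round_trip(self, tmp_path):
        cfg = AnalyzerConfig(rmse_max=77.0, i91_count_min=2)
        cfg.to_yaml(tmp_path / "c.yaml")
        assert AnalyzerConfig.from_yaml(tmp_path / "c.yaml") == cfg

    def test_unknown_keys_rejected(self, tmp_path):
        (tmp_path / "c.yaml").write_text("rmse_max: 50\nbogus_key: 1\n")
        with pytest.raises(ValueError, match="bogus_key"):
            AnalyzerConfig.from_yaml(tmp_path / "c.yaml")
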