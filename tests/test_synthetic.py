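"""Tests for the synthetic cohort generator."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import pulsetrace as pt


def _trace(kin, n_frames=48, seed=0, **spec_kw):
    spec = pt.CellSpec(cell_id="c", kinetics=kin, end_frame=n_frames, **spec_kw)
    return pt.simulate_trace(spec, 15.0, n_frames, rng=np.random.default_rng(seed))


class TestSimulateTrace:
    def test_no_pulsing_no_noise_is_constant_baseline(self):
        kin = pt.PulseKinetics(baseline_mfi=37.5, pulse_fold=1.0, noise_sd_frac=0.0)
        trace, truth = _trace(kin)
        np.testing.assert_allclose(trace.mfi, 37.5)
        assert truth.n_peaks == 0

    @pytest.mark.parametrize("shape", ["sinusoid", "square_convolved"])
    def test_ground_truth_peak_spacing_equals_period(self, shape):
        kin = pt.PulseKinetics(
            pulse_period_h=2.0, pulse_fold=1.6, noise_sd_frac=0.0, pulse_shape=shape
        )
        _, truth = _trace(kin)
        assert truth.n_peaks >= 4
        tol = 1e-9 if shape == "sinusoid" else 0.02
        np.testing.assert_allclose(truth.periods_h, 2.0, atol=tol)

    def test_sample_times_follow_frame_interval(self):
        kin = pt.PulseKinetics(noise_sd_frac=0.0)
        trace, _ = _trace(kin)
        np.testing.assert_allclose(np.diff(trace.times_h), 0.25)
        assert trace.times_h[0] == 0.0

    def test_trace_mean_scales_linearly_with_baseline(self):
        kins = [
            pt.PulseKinetics(baseline_mfi=b, pulse_fold=1.5, noise_sd_frac=0.0)
            for b in (20.0, 60.0)
        ]
        means = [float(_trace(k)[0].mfi.mean()) for k in kins]
        assert means[1] == pytest.approx(3.0 * means[0], rel=1e-9)

    def test_noiseless_fold_matches_requested(self):
        for shape in ("sinusoid", "square_convolved"):
            kin = pt.PulseKinetics(
                pulse_period_h=2.0, pulse_fold=1.7, noise_sd_frac=0.0, pulse_shape=shape
            )
            trace, _ = _trace(kin, n_frames=96)
            fold = trace.mfi.max() / trace.mfi.min()
            assert fold == pytest.approx(1.7, rel=0.03)

    def test_reporter_lag_delays_peaks(self):
        # slower reporter decay => larger phase lag of the observed maxima
        fast = pt.PulseKinetics(reporter_halflife_min=60.0, pulse_fold=1.5)
        slow = pt.PulseKinetics(reporter_halflife_min=120.0, pulse_fold=1.5)
        assert slow.peak_lag_h > fast.peak_lag_h > 0

    def test_bleaching_decays_envelope(self):
        kin = pt.PulseKinetics(pulse_fold=1.0, noise_sd_frac=0.0, bleach_rate_per_h=0.1)
        trace, _ = _trace(kin)
        expected = 45.0 * np.exp(-0.1 * trace.times_h)
        np.testing.assert_allclose(trace.mfi, expected)

    def test_mitosis_dip_is_local_minimum_near_annotated_frame(self):
        kin = pt.PulseKinetics(pulse_fold=1.0, noise_sd_frac=0.0)
        trace, _ = _trace(kin, mitosis_frame=20)
        dip = int(np.argmin(trace.mfi)) + 1  # 1-based frame
        assert abs(dip - 20) <= 2

    def test_noise_sd_tracks_noiseless_mean(self, rng):
        kin = pt.PulseKinetics(baseline_mfi=100.0, pulse_fold=1.0, noise_sd_frac=0.05)
        resid = np.concatenate(
            [_trace(kin, seed=s)[0].mfi - 100.0 for s in range(40)]
        )
        assert np.std(resid) == pytest.approx(5.0, rel=0.1)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"pulse_period_h": 0.0},
            {"pulse_fold": 0.9},
            {"noise_sd_frac": 1.0},
            {"reporter_halflife_min": -5.0},
            {"pulse_shape": "triangle"},
        ],
    )
    def test_invalid_kinetics_raise(self, kwargs):
        with pytest.raises(ValueError):
            pt.PulseKinetics(**kwargs)


class TestSimulateCohort:
    def test_determinism_under_fixed_seed(self):
        config = pt.CohortConfig(
            n_cells_per_subset={"HEC": 5, "BC": 5, "IAHC": 5}, seed=9
        )
        a = pt.simulate_cohort(config)
        b = pt.simulate_cohort(config)
        assert len(a) == len(b) == 15
        for ta, tb in zip(a.traces, b.traces):
            np.testing.assert_array_equal(ta.mfi, tb.mfi)
            np.testing.assert_array_equal(ta.frames, tb.frames)
        assert a.annotations.equals(b.annotations)

    def test_cell_substreams_stable_under_cohort_growth(self):
        small = pt.simulate_cohort(
            pt.CohortConfig(n_cells_per_subset={"HEC": 3, "BC": 0, "IAHC": 0}, seed=4)
        )
        large = pt.simulate_cohort(
            pt.CohortConfig(n_cells_per_subset={"HEC": 6, "BC": 2, "IAHC": 0}, seed=4)
        )
        for ta in small.traces:
            tb = next(t for t in large.traces if t.cell_id == ta.cell_id)
            np.testing.assert_array_equal(ta.mfi, tb.mfi)

    def test_empty_cohort_is_not_an_error(self):
        cohort = pt.simulate_cohort(
            pt.CohortConfig(n_cells_per_subset={"HEC": 0, "BC": 0, "IAHC": 0})
        )
        assert len(cohort) == 0
        assert cohort.annotations.empty

    def test_every_cell_has_labels_and_ground_truth(self, small_cohort):
        assert len(small_cohort.traces) == len(small_cohort.ground_truth) == 36
        for trace, truth in zip(small_cohort.traces, small_cohort.ground_truth):
            assert trace.cell_id == truth.cell_id
            assert trace.subset in pt.SUBSETS
            assert trace.side in pt.SIDES

    def test_halflife_prior_within_reporter_range(self, small_cohort):
        hl = small_cohort.annotations["reporter_halflife_min"]
        assert (hl >= 60.0).all() and (hl <= 120.0).all()

    def test_bc_periods_shorter_than_hec_in_ground_truth(self, default_cohort):
        ann = default_cohort.annotations
        bc = ann.loc[ann.subset == "BC", "true_period_h"].dropna()
        hec = ann.loc[ann.subset == "HEC", "true_period_h"].dropna()
        assert bc.mean() < hec.mean()

    def test_all_nonpulsing_noiseless_cohort_has_zero_detected_peaks(self):
        # synthetic negative control, analogous to a stable nuclear dye
        priors = {
            k: pt.SubsetPrior(
                baseline_mean=50.0, baseline_sd=5.0, pulsing_fraction=0.0,
                noise_sd_frac=0.0,
            )
            for k in pt.SUBSETS
        }
        config = pt.CohortConfig(
            n_cells_per_subset={"HEC": 8, "BC": 8, "IAHC": 8},
            priors=priors, seed=2,
        )
        cohort = pt.simulate_cohort(config)
        for trace in cohort.traces:
            assert pt.detect_peaks(trace) == []

    def test_mitotic_cells_flagged_in_annotations(self, default_cohort):
        ann = default_cohort.annotations
        flagged = ann["mitosis_frame"].notna()
        traces = {t.cell_id: t for t in default_cohort.traces}
        for _, row in ann[flagged].iterrows():
            assert traces[row.cell_id].has_mitosis
        # mitosis should be essentially an IAHC phenomenon under the priors
        assert ann.loc[flagged, "subset"].isin(["IAHC", "BC"]).all()


class TestConfigSerialization:
    def test_yaml_roundtrip_preserves_cohort(self, tmp_path):
        config = pt.CohortConfig(
            n_cells_per_subset={"HEC": 4, "BC": 3, "IAHC": 2}, seed=17, n_frames=30
        )
        path = tmp_path / "cohort.yaml"
        config.to_yaml(path)
        loaded = pt.CohortConfig.from_yaml(path)
        a = pt.simulate_cohort(config)
        b = pt.simulate_cohort(loaded)
        assert len(a) == len(b)
        for ta, tb in zip(a.traces, b.traces):
            np.testing.assert_array_equal(ta.mfi, tb.mfi)

    def test_dict_roundtrip(self):
        config = pt.CohortConfig()
        again = pt.CohortConfig.from_dict(config.to_dict())
        assert again.to_dict() == config.to_dict()


class TestGroundTruthInvariants:
    @given(st.integers(0, 200))
    def test_peak_times_strictly_increasing(self, idx):
        cohort = getattr(TestGroundTruthInvariants, "_cohort", None)
        if cohort is None:
            cohort = pt.simulate_cohort(pt.CohortConfig(seed=13))
            TestGroundTruthInvariants._cohort = cohort
        truth = cohort.ground_truth[idx % len(cohort.ground_truth)]
        assert np.all(np.diff(truth.peak_times_h) > 0)

    def test_noiseless_spacings_within_one_frame_interval(self):
        for period in (1.0, 2.0, 3.0):
            kin = pt.PulseKinetics(
                pulse_period_h=period, pulse_fold=1.5, noise_sd_frac=0.0
            )
            _, truth = _trace(kin)
            assert np.all(np.abs(truth.periods_h - period) <= 0.25)
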