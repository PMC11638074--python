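"""Spectral processing, calibration, assignment and quantification."""

import numpy as np
import pytest

from ubchain.mass_engine import MoietyMassTable, MoietyRow, MassMode
from ubchain.spectral_quant import (
    CalibrationError,
    PeakDetectionParams,
    Peak,
    PeakSet,
    QuantInput,
    QuantResult,
    Spectrum,
    aggregate_replicates,
    assign_peaks,
    calibrate_internal,
    detect_peaks,
    normalize_panel,
    process_spectrum,
    quantify_cleavage,
    quantify_spectrum,
    smooth,
    subtract_baseline,
    read_spectrum,
    write_spectrum,
)
from ubchain.synthetic_data import DEFAULT_METASTABLE, ReactionSpec, SpectrumParams, simulate_assay_spectrum, simulate_spectrum


def make_spectrum(y, start=8000.0, step=0.2):
    mz = start + step * np.arange(len(y))
    return Spectrum(np.asarray(mz), np.asarray(y, dtype=float), window=(mz[0], mz[-1]))


class TestSpectrumType:
    def test_requires_increasing_mz(self):
        with pytest.raises(ValueError):
            Spectrum(np.array([1.0, 1.0, 2.0]), np.zeros(3))

    def test_requires_finite_intensity(self):
        with pytest.raises(ValueError):
            Spectrum(np.array([1.0, 2.0]), np.array([0.0, np.inf]))

    def test_text_io_round_trip(self, tmp_path):
        s = simulate_spectrum([(8600.0, 1.0)], SpectrumParams())
        path = tmp_path / "spec.txt"
        write_spectrum(s, str(path))
        again = read_spectrum(str(path), window=s.window)
        assert np.allclose(again.mz, s.mz) and np.allclose(again.intensity, s.intensity, atol=1e-5)


class TestSmooth:
    def test_cubic_trace_unchanged(self):
        x = np.linspace(-1, 1, 501)
        y = 2.0 + 3 * x - x ** 2 + 0.5 * x ** 3
        s = make_spectrum(y)
        out = smooth(s, PeakDetectionParams(sg_window=51, sg_order=3))
        assert np.allclose(out.intensity, y, atol=1e-8)

    def test_white_noise_variance_reduced(self):
        rng = np.random.default_rng(0)
        y = rng.normal(0, 1, 4001)
        out = smooth(make_spectrum(y), PeakDetectionParams(sg_window=41, sg_order=3))
        assert np.var(out.intensity) < 0.5 * np.var(y)

    def test_delta_spike_area_preserved(self):
        y = np.zeros(1001)
        y[500] = 100.0
        s = make_spectrum(y)
        out = smooth(s, PeakDetectionParams(sg_window=21, sg_order=3))
        assert np.sum(out.intensity) == pytest.approx(np.sum(y), rel=1e-6)

    def test_window_longer_than_trace_rejected(self):
        with pytest.raises(ValueError):
            smooth(make_spectrum(np.zeros(11)), PeakDetectionParams(sg_window=21))

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            PeakDetectionParams(sg_window=20)


class TestBaseline:
    def test_constant_offset_removed(self):
        s = make_spectrum(np.full(2001, 37.5))
        out = subtract_baseline(s, PeakDetectionParams(tophat_width=40.0))
        assert np.allclose(out.intensity, 0.0, atol=1e-9)

    def test_gaussian_on_ramp_area_recovered(self):
        params = SpectrumParams(baseline_offset=20.0, baseline_amplitude=200.0, baseline_scale=500.0)
        s = simulate_spectrum([(8500.0, 1.0)], params)
        out = subtract_baseline(s, PeakDetectionParams(tophat_width=85.0))
        sel = np.abs(out.mz - 8500.0) < 30
        area = np.trapezoid(np.clip(out.intensity[sel], 0, None), out.mz[sel])
        assert area == pytest.approx(params.area_per_conc, rel=0.05)

    def test_baseline_free_trace_nearly_unchanged(self):
        s = simulate_spectrum([(8500.0, 1.0)], SpectrumParams())
        out = subtract_baseline(s, PeakDetectionParams(tophat_width=85.0))
        assert np.trapezoid(out.intensity, out.mz) == pytest.approx(
            np.trapezoid(s.intensity, s.mz), rel=0.05)

    def test_nonpositive_width_rejected(self):
        with pytest.raises(ValueError):
            subtract_baseline(make_spectrum(np.zeros(100)), PeakDetectionParams(tophat_width=0.0))


class TestDetect:
    def test_five_species_found(self, branched_substrate, moiety_table, standard_mz):
        params = SpectrumParams(noise_sd=0.5, baseline_offset=5.0, baseline_amplitude=30.0,
                                seed=4)
        s, _ = simulate_assay_spectrum(ReactionSpec(branched_substrate, 0.6), params)
        peaks = process_spectrum(s)
        assert len(peaks) == 5
        truth_mzs = sorted(list(moiety_table.mzs) + [standard_mz])
        found = sorted(p.centroid for p in peaks.peaks)
        assert np.allclose(found, truth_mzs, atol=0.5)

    def test_noise_only_no_peaks(self):
        s = simulate_spectrum([], SpectrumParams(noise_sd=2.0, seed=42))
        assert len(process_spectrum(s)) == 0

    def test_low_snr_peak_absent(self):
        # peak engineered to sit near S/N 2 after smoothing
        rng_params = SpectrumParams(noise_sd=2.0, seed=9)
        noise_floor = process_spectrum(simulate_spectrum([], rng_params)).noise
        tiny_area = 2 * noise_floor * (8600 / 1000.0 / 2.355) * np.sqrt(2 * np.pi)
        s = simulate_spectrum([(8600.0, tiny_area / rng_params.area_per_conc)], rng_params)
        peaks = process_spectrum(s)
        assert all(abs(p.centroid - 8600.0) > 2 for p in peaks.peaks)

    def test_empty_spectrum_rejected(self):
        with pytest.raises(ValueError):
            detect_peaks(Spectrum(np.array([]), np.array([])))


class TestCalibration:
    @staticmethod
    def peakset(centroids, areas=None):
        areas = areas or [1.0] * len(centroids)
        return PeakSet(tuple(Peak(c, a, 1.0, 10.0, 8.5) for c, a in zip(centroids, areas)),
                       noise=0.1, params=PeakDetectionParams())

    def test_constant_offset_applied(self):
        ps = self.peakset([8565.0, 8671.0])
        cal = calibrate_internal(ps, reference_mz=8669.470)
        assert cal.calibration_shift == pytest.approx(-1.530)
        assert cal.peaks[0].centroid == pytest.approx(8565.0 - 1.530)
        assert cal.peaks[1].centroid == pytest.approx(8669.470)

    def test_already_at_reference_zero_shift(self):
        ps = self.peakset([8669.470])
        cal = calibrate_internal(ps)
        assert cal.calibration_shift == pytest.approx(0.0, abs=1e-12)

    def test_idempotent(self):
        ps = self.peakset([8565.0, 8667.0])
        once = calibrate_internal(ps)
        twice = calibrate_internal(once)
        assert twice.calibration_shift == pytest.approx(once.calibration_shift, abs=1e-12)

    def test_missing_standard_rejected(self):
        ps = self.peakset([8400.0])
        with pytest.raises(CalibrationError):
            calibrate_internal(ps)

    def test_simulated_offset_round_trip(self, branched_substrate, moiety_table, standard_mz):
        params = SpectrumParams(noise_sd=0.5, calibration_offset=2.0, seed=8)
        s, _ = simulate_assay_spectrum(ReactionSpec(branched_substrate, 0.5), params)
        cal = calibrate_internal(process_spectrum(s), reference_mz=standard_mz)
        for mz in moiety_table.mzs:
            nearest = cal.nearest(mz)
            assert abs(nearest.centroid - mz) < 0.3


class TestAssignment:
    TABLE = MoietyMassTable(tuple(
        MoietyRow(f"u{i}", "ctx", mz, MassMode.AVERAGE)
        for i, mz in enumerate([8182.3, 8565.8, 8621.8], start=1)))

    def test_nearest_within_tolerance(self):
        ps = TestCalibration.peakset([8182.4, 8565.9])
        res = assign_peaks(ps, self.TABLE, tolerance=2.0)
        assert set(res.assigned) == {"u1", "u2"}
        assert not res.unassigned

    def test_far_peaks_unassigned(self):
        ps = TestCalibration.peakset([8400.0])
        res = assign_peaks(ps, self.TABLE, tolerance=2.0)
        assert not res.assigned and len(res.unassigned) == 1

    def test_conflict_largest_area_wins(self):
        ps = TestCalibration.peakset([8565.5, 8566.0], areas=[1.0, 5.0])
        res = assign_peaks(ps, self.TABLE, tolerance=2.0)
        assert res.assigned["u2"].area == 5.0
        assert len(res.conflicts) == 1

    def test_ambiguous_table_rejected(self):
        table = MoietyMassTable((
            MoietyRow("a", "c", 8565.0, MassMode.AVERAGE),
            MoietyRow("b", "c", 8567.0, MassMode.AVERAGE)))
        with pytest.raises(ValueError):
            assign_peaks(TestCalibration.peakset([8565.0]), table, tolerance=2.0)


class TestQuantify:
    def test_equal_areas_equal_concs_is_100(self):
        assert quantify_cleavage(QuantInput(5.0, 5.0, 1.0, 1.0)) == pytest.approx(100.0)

    def test_methods_equation_substitution(self):
        # area ratio 0.5 with the default 0.8/0.96 concentration ratio
        assert quantify_cleavage(QuantInput(0.5, 1.0)) == pytest.approx(41.7, abs=0.05)

    def test_zero_area_is_zero_percent(self):
        assert quantify_cleavage(QuantInput(0.0, 1.0)) == 0.0

    def test_zero_standard_rejected(self):
        with pytest.raises(ValueError):
            quantify_cleavage(QuantInput(1.0, 0.0))

    def test_over_100_retained_not_clipped(self):
        val = quantify_cleavage(QuantInput(3.0, 1.0, 1.0, 1.0))
        assert val == pytest.approx(300.0)

    def test_global_rescale_invariance(self, branched_substrate, moiety_table, standard_mz):
        params = SpectrumParams(noise_sd=0.0, baseline_offset=0.0, seed=0)
        s, _ = simulate_assay_spectrum(ReactionSpec(branched_substrate, 0.5), params)
        r1 = quantify_spectrum(s, moiety_table, standard_mz=standard_mz)
        scaled = Spectrum(s.mz, s.intensity * 7.3, window=s.window)
        r2 = quantify_spectrum(scaled, moiety_table, standard_mz=standard_mz)
        for k in r1:
            assert r2[k] == pytest.approx(r1[k], rel=1e-6)

    def test_pipeline_deterministic(self, branched_substrate, moiety_table, standard_mz):
        params = SpectrumParams(noise_sd=1.0, seed=3, metastable=DEFAULT_METASTABLE)
        s, _ = simulate_assay_spectrum(ReactionSpec(branched_substrate, 0.5), params)
        r1 = quantify_spectrum(s, moiety_table, standard_mz=standard_mz)
        r2 = quantify_spectrum(s, moiety_table, standard_mz=standard_mz)
        assert r1 == r2


class TestPanel:
    RESULTS = [
        QuantResult("DUB1", "ctrl", "m1", (40.0, 60.0), is_control=True),
        QuantResult("DUB1", "sub", "m1", (20.0, 30.0)),
        QuantResult("DUB2", "ctrl", "m1", (10.0, 10.0), is_control=True),
        QuantResult("DUB2", "sub", "m1", (30.0, 30.0)),
    ]

    def test_raw_mode(self):
        matrix, flags = normalize_panel(self.RESULTS, "none")
        assert matrix.loc["DUB1", ("ctrl", "m1")] == pytest.approx(50.0)
        assert not flags

    def test_control_substrate_mode(self):
        matrix, flags = normalize_panel(self.RESULTS, "control_substrate")
        assert matrix.loc["DUB1", ("ctrl", "m1")] == pytest.approx(1.0)
        assert matrix.loc["DUB1", ("sub", "m1")] == pytest.approx(0.5)
        assert matrix.loc["DUB2", ("sub", "m1")] == pytest.approx(3.0)

    def test_distal_48ub3_mode(self):
        results = [
            QuantResult("MINDY1", "48Ub3", "distal", (10.0, 10.0), is_distal_48ub3=True),
            QuantResult("MINDY1", "branched", "arm48", (54.0, 54.0)),
        ]
        matrix, flags = normalize_panel(results, "distal_48Ub3")
        assert matrix.loc["MINDY1", ("branched", "arm48")] == pytest.approx(5.4)

    def test_missing_reference_flagged_not_dropped(self):
        results = [QuantResult("DUBX", "sub", "m1", (5.0,))]
        matrix, flags = normalize_panel(results, "control_substrate")
        assert flags == ["DUBX"]
        assert np.isnan(matrix.loc["DUBX", ("sub", "m1")])

    def test_zero_reference_flagged(self):
        results = [
            QuantResult("DUBZ", "ctrl", "m1", (0.0, 0.0), is_control=True),
            QuantResult("DUBZ", "sub", "m1", (5.0, 5.0)),
        ]
        _, flags = normalize_panel(results, "control_substrate")
        assert flags == ["DUBZ"]

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            normalize_panel(self.RESULTS, "per_row")

    def test_aggregate_keeps_replicates(self):
        heatmap, points = aggregate_replicates(self.RESULTS[:1])
        assert heatmap.loc["DUB1", ("ctrl", "m1")] == pytest.approx(50.0)
        assert sorted(points["percent"]) == [40.0, 60.0]

    def test_single_replicate_flagged_n1(self):
        heatmap, points = aggregate_replicates([QuantResult("D", "s", "m", (70.0,))])
        assert heatmap.loc["D", ("s", "m")] == pytest.approx(70.0)
        assert (points["n"] == 1).all()

    def test_panel_matches_hand_computed_means(self):
        heatmap, _ = aggregate_replicates(self.RESULTS)
        for r in self.RESULTS:
            assert heatmap.loc[r.dub, (r.substrate, r.moiety)] == pytest.approx(
                sum(r.replicates) / len(r.replicates))
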