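"""Peak-quality measurements: baseline, noise, apex, widths, skewness,
area, SNR, replicate ΔtR, and the composite quality row."""

import math

import numpy as np
import pytest
from conftest import make_peak_chrom, mirror_chrom
from hypothesis import given
from hypothesis import strategies as st

from chromqc.chromatogram import Chromatogram
from chromqc.errors import (
    DegeneratePeakError,
    NoiseError,
    NoPeakError,
    ParameterError,
    UnresolvedPeakError,
)
from chromqc.metrics import (
    compute_delta_tr,
    detect_apex,
    estimate_baseline,
    estimate_noise_sd,
    half_height_widths,
    measure_area,
    measure_peak,
    measure_single_peak,
    measure_skewness,
    measure_snr,
)

FWHM_HALF = math.sqrt(2 * math.log(2))  # sigma multiplier for one half-width


def flat_chrom(value=5.0, n=2000, noise_sd=0.0, slope=0.0, seed=0):
    t = np.arange(n) * 0.01
    rng = np.random.default_rng(seed)
    return Chromatogram(t, value + slope * t + rng.normal(0, noise_sd, n))


class TestBaselineAndNoise:
    def test_flat_signal_recovered_exactly(self):
        chrom = flat_chrom(5.0)
        assert np.allclose(estimate_baseline(chrom), 5.0, atol=1e-9)

    def test_sloped_baseline_recovered_exactly(self):
        chrom = flat_chrom(2.0, slope=0.1)
        base = estimate_baseline(chrom)
        assert np.allclose(base, 2.0 + 0.1 * chrom.time, atol=1e-9)

    def test_noisy_sloped_baseline_with_peak_excluded(self):
        chrom = make_peak_chrom(height=500, intercept=2.0, slope=0.1,
                                noise_sd=1.0, seed=3, grid=(0, 25, 0.005))
        base = estimate_baseline(chrom, [(8.0, 12.0)])
        n_idle = int((~((chrom.time >= 8) & (chrom.time <= 12))).sum())
        # intercept standard error for a noise-sd-1 regression on n points
        se = 1.0 / math.sqrt(n_idle) * 2.2  # conservative multiplier
        assert abs(base[0] - 2.0) < 3 * se

    def test_too_few_idle_points_rejected(self):
        chrom = flat_chrom(5.0, n=100)
        with pytest.raises(Exception):
            estimate_baseline(chrom, [(0.0, 0.99)])

    def test_noiseless_noise_sd_is_zero(self):
        chrom = flat_chrom(5.0, slope=0.3)
        base = estimate_baseline(chrom)
        assert estimate_noise_sd(chrom, base) < 1e-12

    def test_injected_noise_recovered_within_5pct(self):
        chrom = flat_chrom(5.0, n=10000, noise_sd=2.0, seed=1)
        base = estimate_baseline(chrom)
        assert estimate_noise_sd(chrom, base) == pytest.approx(2.0, rel=0.05)

    def test_noise_sd_invariant_under_linear_baseline(self):
        a = flat_chrom(0.0, n=5000, noise_sd=1.5, seed=2)
        b = Chromatogram(a.time, a.intensity + 7.0 + 0.4 * a.time)
        sd_a = estimate_noise_sd(a, estimate_baseline(a))
        sd_b = estimate_noise_sd(b, estimate_baseline(b))
        assert sd_a == pytest.approx(sd_b, rel=1e-9)

    def test_noise_needs_enough_idle_points(self):
        chrom = flat_chrom(5.0, n=2000)
        base = estimate_baseline(chrom, [(0.0, 17.0)])
        with pytest.raises(NoiseError):
            estimate_noise_sd(chrom, base, [(0.0, 19.9)])


class TestDetectApex:
    def test_subgrid_apex_on_dense_grid(self):
        # True apex placed off-grid; the parabolic refinement must recover
        # it far below the sampling interval.
        chrom = make_peak_chrom(apex=10.0012, height=100.0)
        base = np.zeros(len(chrom))
        apex_time, apex_height = detect_apex(chrom, base)
        assert apex_time == pytest.approx(10.0012, abs=1e-4)
        assert apex_height == pytest.approx(100.0, rel=1e-3)

    def test_two_windows_isolate_two_peaks(self):
        from chromqc.simulate import PeakSpec, RunSpec, render_chromatogram

        run = RunSpec(0, 25, 0.005,
                      peaks=(PeakSpec("a", 8.0, 100, 0.1), PeakSpec("b", 15.0, 60, 0.1)))
        chrom = render_chromatogram(run)
        base = np.zeros(len(chrom))
        t1, h1 = detect_apex(chrom, base, (6, 10))
        t2, h2 = detect_apex(chrom, base, (13, 17))
        assert t1 == pytest.approx(8.0, abs=1e-3) and h1 == pytest.approx(100, rel=1e-3)
        assert t2 == pytest.approx(15.0, abs=1e-3) and h2 == pytest.approx(60, rel=1e-3)

    def test_all_zero_signal_raises_no_peak(self):
        t = np.arange(0, 10, 0.01)
        chrom = Chromatogram(t, np.zeros(len(t)))
        with pytest.raises(NoPeakError):
            detect_apex(chrom, np.zeros(len(t)))

    def test_apex_below_snr_floor_raises(self):
        chrom = make_peak_chrom(height=5.0)
        with pytest.raises(NoPeakError):
            detect_apex(chrom, np.zeros(len(chrom)), noise_sd=2.0, snr_floor=3.0)


class TestWidthsAndSkewness:
    def test_gaussian_fwhm_closed_form(self):
        chrom = make_peak_chrom(height=100.0, sigma=0.1)
        base = np.zeros(len(chrom))
        wl, wr = half_height_widths(chrom, base, 10.0, 100.0, 0.5)
        assert wl == pytest.approx(0.1 * FWHM_HALF, rel=5e-3)
        assert wr == pytest.approx(0.1 * FWHM_HALF, rel=5e-3)

    def test_triangular_peak_linear_geometry(self):
        t = np.arange(0, 25, 0.005)
        y = np.interp(t, [9.0, 10.0, 13.0], [0.0, 2.0, 0.0], left=0, right=0)
        chrom = Chromatogram(t, y)
        wl, wr = half_height_widths(chrom, np.zeros(len(t)), 10.0, 2.0, 0.5)
        assert wl == pytest.approx(0.5, abs=1e-9)
        assert wr == pytest.approx(1.5, abs=1e-9)
        assert measure_skewness(wl, wr) == pytest.approx(3.0, abs=1e-9)

    def test_apex_at_edge_unresolved(self):
        t = np.arange(0, 10, 0.01)
        y = np.exp(-((t - 0.05) ** 2) / (2 * 0.5**2))  # apex at the grid edge
        chrom = Chromatogram(t, y)
        with pytest.raises(UnresolvedPeakError):
            half_height_widths(chrom, np.zeros(len(t)), 0.05, 1.0, 0.5)

    def test_symmetric_peak_skewness_is_one(self):
        assert measure_skewness(0.7, 0.7) == pytest.approx(1.0)

    def test_zero_left_width_rejected(self):
        with pytest.raises(DegeneratePeakError):
            measure_skewness(0.0, 1.0)

    @pytest.mark.parametrize("tau", [0.05, 0.1, 0.2])
    def test_mirrored_chromatogram_reciprocal_skewness(self, tau):
        chrom = make_peak_chrom(height=100.0, sigma=0.08, tau=tau)
        q = measure_single_peak(chrom).skewness
        q_mirror = measure_single_peak(mirror_chrom(chrom)).skewness
        assert q_mirror == pytest.approx(1.0 / q, abs=1e-6)

    def test_skewness_approaches_one_as_tailing_vanishes(self):
        skews = []
        for tau in (0.2, 0.1, 0.05, 0.01):
            chrom = make_peak_chrom(height=100.0, sigma=0.1, tau=tau)
            skews.append(measure_single_peak(chrom).skewness)
        assert all(a > b for a, b in zip(skews, skews[1:]))
        assert skews[-1] == pytest.approx(1.0, abs=0.05)
        assert all(s > 1 for s in skews)


class TestArea:
    def test_zero_signal_zero_area(self):
        t = np.arange(0, 10, 0.01)
        chrom = Chromatogram(t, np.zeros(len(t)))
        assert measure_area(chrom, np.zeros(len(t)), 2.0, 8.0) == 0.0

    def test_gaussian_area_closed_form(self):
        chrom = make_peak_chrom(height=1.0, sigma=0.1)
        area = measure_area(chrom, np.zeros(len(chrom)), 10 - 0.6, 10 + 0.6)
        assert area == pytest.approx(0.1 * math.sqrt(2 * math.pi), rel=5e-3)

    def test_area_linear_in_height(self):
        base = np.zeros(len(make_peak_chrom()))
        a1 = measure_area(make_peak_chrom(height=50), base, 9, 11)
        a2 = measure_area(make_peak_chrom(height=100), base, 9, 11)
        assert a2 == pytest.approx(2 * a1, rel=1e-9)

    def test_inverted_bounds_rejected(self):
        chrom = make_peak_chrom()
        with pytest.raises(ParameterError):
            measure_area(chrom, np.zeros(len(chrom)), 11.0, 9.0)


class TestSnr:
    def test_simple_ratio(self):
        assert measure_snr(100.0, 4.0) == 25.0

    def test_zero_noise_gives_infinity_sentinel(self):
        assert math.isinf(measure_snr(10.0, 0.0))

    def test_negative_noise_rejected(self):
        with pytest.raises(ParameterError):
            measure_snr(10.0, -1.0)

    def test_scale_invariance_of_measured_snr(self):
        chrom = make_peak_chrom(height=80.0, noise_sd=2.0, seed=4)
        scaled = Chromatogram(chrom.time, chrom.intensity * 3.7)
        snr_a = measure_single_peak(chrom).snr
        snr_b = measure_single_peak(scaled).snr
        assert snr_b == pytest.approx(snr_a, rel=1e-9)

    def test_end_to_end_snr_recovery(self):
        chrom = make_peak_chrom(height=50.0, noise_sd=2.0, seed=6, grid=(0, 25, 0.002))
        assert measure_single_peak(chrom).snr == pytest.approx(25.0, rel=0.10)


class TestDeltaTr:
    def test_equal_runs_zero(self):
        assert compute_delta_tr("c", 8.26, 8.26).delta == 0.0

    def test_sign_convention_second_run_later(self):
        assert compute_delta_tr("c", 10.0, 10.5).delta == pytest.approx(-0.5)

    @given(st.floats(0.1, 24.0), st.floats(0.1, 24.0))
    def test_antisymmetry(self, a, b):
        assert compute_delta_tr("c", a, b).delta == pytest.approx(
            -compute_delta_tr("c", b, a).delta
        )

    def test_missing_replicate_yields_nan_sentinel(self):
        d = compute_delta_tr("c", float("nan"), 10.0)
        assert math.isnan(d.delta)


class TestMeasurePeakComposite:
    def test_noiseless_symmetric_pair(self):
        c1 = make_peak_chrom(height=100.0)
        c2 = make_peak_chrom(height=100.0)
        row = measure_peak(c1, c2, "c")
        assert row.measurement.skewness == pytest.approx(1.0, abs=1e-6)
        assert row.delta_tr.delta == pytest.approx(0.0, abs=1e-9)

    def test_baseline_invariance_of_snr_and_skewness(self):
        plain = make_peak_chrom(height=80.0, tau=0.1, noise_sd=1.0, seed=8)
        drifted = Chromatogram(plain.time, plain.intensity + 6.0 + 0.3 * plain.time)
        ma = measure_single_peak(plain)
        mb = measure_single_peak(drifted)
        assert mb.snr == pytest.approx(ma.snr, rel=1e-6)
        assert mb.skewness == pytest.approx(ma.skewness, rel=1e-6)
        assert mb.area == pytest.approx(ma.area, rel=1e-6)

    def test_failed_second_run_flags_row(self):
        c1 = make_peak_chrom(height=100.0)
        t = np.arange(0, 25, 0.005)
        dead = Chromatogram(t, np.zeros(len(t)))
        row = measure_peak(c1, dead, "c")
        assert not row.ok
        assert row.delta_tr is None
        assert row.measurement is not None  # run-1 metrics survive

    def test_measured_tr_tracks_injected_tr(self):
        for seed, apex in ((1, 9.317), (2, 14.552)):
            chrom = make_peak_chrom(apex=apex, height=300, noise_sd=1.0, seed=seed)
            m = measure_single_peak(chrom)
            assert abs(m.apex_time - apex) < 3 * 0.005
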