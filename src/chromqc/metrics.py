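"""Peak-quality measurements from chromatographic signals.

Four measurements characterise the quality of a detected peak:

* **SNR** — apex height above the baseline divided by the standard deviation
  of the baseline-detrended noise in the idle (peak-free) region.
* **ΔtR** — signed retention-time difference between two replicate runs,
  tR,1 − tR,2; a negative value means the compound eluted later in run 2.
* **Skewness** Qs,0(x) = WR(x) / WL(x) — the ratio of the right to the left
  half-width of the peak measured at fraction ``x`` (default 0.5) of the apex
  height.  1 means symmetric, values below 1 a fronting peak, above 1 a
  tailing peak.
* **Peak area** — trapezoidal integral of the baseline-subtracted signal
  over the integration window.

The baseline is fit linearly to idle points; all measurements are taken on
the baseline-subtracted signal, which makes SNR and skewness invariant under
affine baseline drift.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .chromatogram import Chromatogram
from .errors import (
    BaselineError,
    DegeneratePeakError,
    NoiseError,
    NoPeakError,
    ParameterError,
    UnresolvedPeakError,
)

#: Minimum multiple of the noise sd the apex must rise above the baseline.
DEFAULT_SNR_FLOOR = 3.0
#: Half-width, in minutes, of the window excluded around a rough peak
#: location when fitting the baseline to idle points.
DEFAULT_EXCLUSION_HALF_WIDTH = 2.0

MIN_IDLE_FRACTION = 0.10
MIN_IDLE_POINTS_NOISE = 16


@dataclass(frozen=True)
class PeakMeasurement:
    """All quality measurements for one detected peak."""

    apex_time: float  # minutes (tR)
    apex_height: float  # intensity above baseline
    wl: float  # minutes, apex -> left crossing at fraction x
    wr: float  # minutes, apex -> right crossing at fraction x
    skewness: float  # Qs,0 = wr / wl
    area: float  # intensity * minutes
    snr: float  # apex_height / noise_sd
    noise_sd: float  # intensity
    left_bound: float  # minutes, integration window
    right_bound: float  # minutes
    x_fraction: float = 0.5


@dataclass(frozen=True)
class DeltaTr:
    """Replicate retention-time difference for one compound."""

    compound_id: str
    tr_run1: float
    tr_run2: float
    delta: float  # tr_run1 - tr_run2


@dataclass
class PeakRow:
    """One Table-style quality row: measurement, ΔtR and failure flags."""

    compound_id: str
    measurement: PeakMeasurement | None
    delta_tr: DeltaTr | None
    flags: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.flags


# ---------------------------------------------------------------------------
# baseline and noise


def _idle_mask(chrom: Chromatogram, exclusion_windows) -> np.ndarray:
    mask = np.ones(len(chrom), dtype=bool)
    for lo, hi in exclusion_windows:
        mask &= ~((chrom.time >= lo) & (chrom.time <= hi))
    return mask


def estimate_baseline(chrom: Chromatogram, exclusion_windows=()) -> np.ndarray:
    """Linear baseline fit to points outside the exclusion windows,
    returned on the full time grid."""
    mask = _idle_mask(chrom, exclusion_windows)
    n_idle = int(mask.sum())
    if n_idle < max(2, int(MIN_IDLE_FRACTION * len(chrom))):
        raise BaselineError(
            f"only {n_idle}/{len(chrom)} idle points left for the baseline fit"
        )
    slope, intercept = np.polyfit(chrom.time[mask], chrom.intensity[mask], 1)
    return intercept + slope * chrom.time


def estimate_noise_sd(chrom: Chromatogram, baseline, exclusion_windows=()) -> float:
    """Sample sd of (intensity − baseline) over the idle points."""
    mask = _idle_mask(chrom, exclusion_windows)
    n_idle = int(mask.sum())
    if n_idle < MIN_IDLE_POINTS_NOISE:
        raise NoiseError(f"only {n_idle} idle points; need {MIN_IDLE_POINTS_NOISE}")
    residual = chrom.intensity[mask] - np.asarray(baseline)[mask]
    return float(np.std(residual, ddof=1))


# ---------------------------------------------------------------------------
# apex


def detect_apex(
    chrom: Chromatogram,
    baseline,
    search_window=None,
    noise_sd: float = 0.0,
    snr_floor: float = DEFAULT_SNR_FLOOR,
):
    """Locate the peak apex inside ``search_window``.

    The apex is the maximum of the baseline-subtracted signal; its position
    and height are refined by a 3-point parabolic fit through the grid
    maximum and its neighbours, giving sub-grid retention-time precision.

    Raises :class:`NoPeakError` when the apex does not rise more than
    ``snr_floor * noise_sd`` above the baseline.
    """
    signal = chrom.intensity - np.asarray(baseline)
    if search_window is None:
        lo_i, hi_i = 0, len(chrom) - 1
    else:
        lo, hi = search_window
        if lo >= hi:
            raise ParameterError("search window must satisfy lo < hi")
        idx = np.nonzero((chrom.time >= lo) & (chrom.time <= hi))[0]
        if len(idx) < 3:
            raise ParameterError("search window contains fewer than 3 grid points")
        lo_i, hi_i = int(idx[0]), int(idx[-1])
    win = signal[lo_i : hi_i + 1]
    i = int(np.argmax(win)) + lo_i
    height = float(signal[i])
    if height <= snr_floor * noise_sd:
        raise NoPeakError(
            f"apex height {height:.4g} does not exceed {snr_floor} x noise {noise_sd:.4g}"
        )
    apex_time = float(chrom.time[i])
    apex_height = height
    if lo_i < i < hi_i:
        y0, y1, y2 = signal[i - 1], signal[i], signal[i + 1]
        denom = y0 - 2.0 * y1 + y2
        if denom < 0:  # strict local curvature; otherwise keep the grid point
            delta = 0.5 * (y0 - y2) / denom
            if abs(delta) <= 1.0:
                dt = chrom.sampling_interval
                apex_time = float(chrom.time[i] + delta * dt)
                apex_height = float(y1 - 0.25 * (y0 - y2) * delta)
    return apex_time, apex_height


# ---------------------------------------------------------------------------
# widths, skewness, area


def half_height_widths(
    chrom: Chromatogram,
    baseline,
    apex_time: float,
    apex_height: float,
    x: float = 0.5,
    search_window=None,
):
    """Half-widths WL(x), WR(x): horizontal distances from the vertical line
    through the apex to the first crossings of ``x * apex_height`` moving
    left and right, located by linear interpolation between grid points."""
    if not (0.0 < x < 1.0):
        raise ParameterError("x must lie in (0, 1)")
    if apex_height <= 0:
        raise DegeneratePeakError("apex height must be > 0")
    signal = chrom.intensity - np.asarray(baseline)
    if search_window is None:
        lo_i, hi_i = 0, len(chrom) - 1
    else:
        idx = np.nonzero((chrom.time >= search_window[0]) & (chrom.time <= search_window[1]))[0]
        if len(idx) < 3:
            raise ParameterError("search window contains fewer than 3 grid points")
        lo_i, hi_i = int(idx[0]), int(idx[-1])
    target = x * apex_height
    i_apex = int(np.clip(np.searchsorted(chrom.time, apex_time), lo_i + 1, hi_i))

    def _cross(direction: int) -> float:
        # Walk outward from the apex; first grid point at or below target
        # brackets the crossing.  A point exactly on the target is taken as
        # the crossing itself (inner tie-break).
        i = i_apex if direction > 0 else i_apex - 1
        prev = None
        while lo_i <= i <= hi_i:
            if signal[i] <= target:
                if prev is None or signal[i] == target:
                    return float(chrom.time[i])
                t0, t1 = chrom.time[prev], chrom.time[i]
                y0, y1 = signal[prev], signal[i]
                return float(t0 + (target - y0) * (t1 - t0) / (y1 - y0))
            prev = i
            i += direction
        side = "right" if direction > 0 else "left"
        raise UnresolvedPeakError(
            f"signal never falls below {x:g} x apex height on the {side} side"
        )

    t_right = _cross(+1)
    t_left = _cross(-1)
    wl = apex_time - t_left
    wr = t_right - apex_time
    if wl <= 0 or wr <= 0:
        raise DegeneratePeakError("non-positive half-width")
    return wl, wr


def measure_skewness(wl: float, wr: float) -> float:
    """Qs,0(x) = WR(x) / WL(x); 1 = symmetric, <1 fronting, >1 tailing."""
    if wl <= 0:
        raise DegeneratePeakError("left half-width must be > 0")
    return wr / wl


def find_integration_bounds(
    chrom: Chromatogram,
    baseline,
    apex_time: float,
    apex_height: float,
    noise_sd: float = 0.0,
    search_window=None,
):
    """Integration window: walk outward from the apex until the baseline-
    subtracted signal first falls below max(0.5 * noise_sd, 1e-12 * height),
    capped at the search window."""
    signal = chrom.intensity - np.asarray(baseline)
    if search_window is None:
        lo_i, hi_i = 0, len(chrom) - 1
    else:
        idx = np.nonzero((chrom.time >= search_window[0]) & (chrom.time <= search_window[1]))[0]
        lo_i, hi_i = int(idx[0]), int(idx[-1])
    floor = max(0.5 * noise_sd, 1e-12 * apex_height)
    i_apex = int(np.clip(np.searchsorted(chrom.time, apex_time), lo_i, hi_i))
    left = lo_i
    for i in range(i_apex, lo_i - 1, -1):
        if signal[i] < floor:
            left = i
            break
    right = hi_i
    for i in range(i_apex, hi_i + 1):
        if signal[i] < floor:
            right = i
            break
    return float(chrom.time[left]), float(chrom.time[right])


def measure_area(
    chrom: Chromatogram, baseline, left_bound: float, right_bound: float
) -> float:
    """Trapezoidal integral of max(intensity − baseline, 0) over
    [left_bound, right_bound]."""
    if left_bound >= right_bound:
        raise ParameterError("left_bound must be < right_bound")
    mask = (chrom.time >= left_bound) & (chrom.time <= right_bound)
    if mask.sum() < 2:
        raise ParameterError("integration window contains fewer than 2 grid points")
    residual = np.clip(chrom.intensity[mask] - np.asarray(baseline)[mask], 0.0, None)
    return float(np.trapezoid(residual, chrom.time[mask]))


def measure_snr(apex_height: float, noise_sd: float) -> float:
    """SNR = apex height above baseline / noise sd.  A noiseless signal
    yields +inf, which downstream assembly flags rather than propagates."""
    if noise_sd < 0:
        raise ParameterError("noise_sd must be >= 0")
    if noise_sd == 0:
        return math.inf
    return apex_height / noise_sd


def compute_delta_tr(compound_id: str, tr_run1: float, tr_run2: float) -> DeltaTr:
    """ΔtR = tR,1 − tR,2 (signed; negative means run 2 eluted later)."""
    if tr_run1 is None or tr_run2 is None or not (
        np.isfinite(tr_run1) and np.isfinite(tr_run2)
    ):
        return DeltaTr(compound_id, float("nan"), float("nan"), float("nan"))
    if tr_run1 <= 0 or tr_run2 <= 0:
        raise ParameterError("retention times must be > 0")
    return DeltaTr(compound_id, tr_run1, tr_run2, tr_run1 - tr_run2)


# ---------------------------------------------------------------------------
# composite measurement


def measure_single_peak(
    chrom: Chromatogram,
    search_window=None,
    x: float = 0.5,
    exclusion_half_width: float = DEFAULT_EXCLUSION_HALF_WIDTH,
    snr_floor: float = DEFAULT_SNR_FLOOR,
) -> PeakMeasurement:
    """Full measurement of the single dominant peak in one chromatogram.

    The peak region is located from the raw maximum, excluded from a linear
    baseline fit, and all metrics are computed on the baseline-subtracted
    signal.
    """
    # Rough peak location on the raw signal (before any baseline correction)
    # just to carve out the exclusion window for the baseline fit.
    rough_t = float(chrom.time[np.argmax(chrom.intensity)])
    exclusion = [(rough_t - exclusion_half_width, rough_t + exclusion_half_width)]
    baseline = estimate_baseline(chrom, exclusion)
    noise_sd = estimate_noise_sd(chrom, baseline, exclusion)
    apex_time, apex_height = detect_apex(
        chrom, baseline, search_window, noise_sd=noise_sd, snr_floor=snr_floor
    )
    wl, wr = half_height_widths(chrom, baseline, apex_time, apex_height, x, search_window)
    left, right = find_integration_bounds(
        chrom, baseline, apex_time, apex_height, noise_sd, search_window
    )
    area = measure_area(chrom, baseline, left, right)
    return PeakMeasurement(
        apex_time=apex_time,
        apex_height=apex_height,
        wl=wl,
        wr=wr,
        skewness=measure_skewness(wl, wr),
        area=area,
        snr=measure_snr(apex_height, noise_sd),
        noise_sd=noise_sd,
        left_bound=left,
        right_bound=right,
        x_fraction=x,
    )


def measure_peak(
    chrom_run1: Chromatogram,
    chrom_run2: Chromatogram,
    compound_id: str,
    search_window=None,
    x: float = 0.5,
    **kwargs,
) -> PeakRow:
    """Measure a replicate pair into one quality row.

    Run 1 supplies SNR, skewness, area and tR; run 2 contributes only tR,2
    for ΔtR.  A failed metric is recorded as missing and the row is flagged
    with the failure reason instead of raising.
    """
    flags = []
    measurement = None
    tr1 = float("nan")
    try:
        measurement = measure_single_peak(chrom_run1, search_window, x, **kwargs)
        tr1 = measurement.apex_time
    except Exception as exc:  # noqa: BLE001 - flag, don't crash the cohort
        flags.append(f"run1: {exc}")
    tr2 = float("nan")
    try:
        rough2 = float(chrom_run2.time[np.argmax(chrom_run2.intensity)])
        excl2 = [(rough2 - DEFAULT_EXCLUSION_HALF_WIDTH, rough2 + DEFAULT_EXCLUSION_HALF_WIDTH)]
        baseline2 = estimate_baseline(chrom_run2, excl2)
        noise2 = estimate_noise_sd(chrom_run2, baseline2, excl2)
        tr2, _ = detect_apex(
            chrom_run2, baseline2, search_window, noise_sd=noise2,
            snr_floor=kwargs.get("snr_floor", DEFAULT_SNR_FLOOR),
        )
    except Exception as exc:  # noqa: BLE001
        flags.append(f"run2: {exc}")
    delta = compute_delta_tr(compound_id, tr1, tr2) if np.isfinite(tr1) and np.isfinite(tr2) else None
    if delta is None:
        flags.append("delta_tr: missing replicate retention time")
    if measurement is not None and not np.isfinite(measurement.snr):
        flags.append("snr: infinite (zero noise)")
    return PeakRow(compound_id=compound_id, measurement=measurement, delta_tr=delta, flags=flags)
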