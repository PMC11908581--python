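"""Synthetic chromatogram generator with known ground truth.

The detector signal is composed as Y(t) = B(t) + P(t) + N(t): a linear
baseline, a sum of chromatographic peaks, and i.i.d. Gaussian noise.  Peaks
follow the exponentially modified Gaussian (EMG) model — the standard shape
for real chromatographic peaks, which are typically tailing — parameterised
by the height of the underlying tau=0 Gaussian so that the integrated area
``height * sigma * sqrt(2*pi)`` is invariant under the tailing constant tau
(convolution with a normalised exponential preserves area).

Cohorts of compounds are generated in three latent quality tiers
(high / medium / low) that differ in noise level, peak tailing, replicate
retention-time jitter and signal strength.  The tier label is recorded as
ground truth so the downstream clustering and per-cluster validation stages
can be scored against it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import erfc, erfcx

from .chromatogram import CSV_FLOAT_FORMAT, Chromatogram
from .errors import ParameterError

_SQRT2 = math.sqrt(2.0)
_SQRT_HALF_PI = math.sqrt(math.pi / 2.0)

TIERS = ("high", "medium", "low")

#: Truth-table CSV column order (the external interface).
TRUTH_COLUMNS = [
    "compound_id",
    "length",
    "sulfur_count",
    "tier",
    "true_tr_run1",
    "true_tr_run2",
    "noise_sd",
    "tau",
    "height",
]


# ---------------------------------------------------------------------------
# specs


@dataclass(frozen=True)
class PeakSpec:
    """One chromatographic peak: an EMG with Gaussian core height ``height``,
    width ``sigma`` and exponential tailing constant ``tau`` (0 = symmetric)."""

    compound_id: str
    apex_time: float  # minutes (apex of the tau=0 Gaussian)
    height: float  # intensity units
    sigma: float  # minutes
    tau: float = 0.0  # minutes

    def __post_init__(self):
        vals = (self.apex_time, self.height, self.sigma, self.tau)
        if not all(np.isfinite(v) for v in vals):
            raise ParameterError("peak parameters must be finite")
        if self.height <= 0:
            raise ParameterError("height must be > 0")
        if self.sigma <= 0:
            raise ParameterError("sigma must be > 0")
        if self.tau < 0:
            raise ParameterError("tau must be >= 0")


@dataclass(frozen=True)
class RunSpec:
    """One chromatographic run: time window, peaks, baseline and noise."""

    time_start: float
    time_end: float
    sampling_interval: float
    peaks: tuple = ()
    baseline_intercept: float = 0.0
    baseline_slope: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.time_end <= self.time_start:
            raise ParameterError("time_end must exceed time_start")
        if self.sampling_interval <= 0:
            raise ParameterError("sampling_interval must be > 0")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        object.__setattr__(self, "peaks", tuple(self.peaks))
        for p in self.peaks:
            if not (self.time_start <= p.apex_time <= self.time_end):
                raise ParameterError(
                    f"peak {p.compound_id!r} apex {p.apex_time} outside the run window"
                )


@dataclass(frozen=True)
class CompoundSpec:
    """A compound to be injected: an oligonucleotide of given length with a
    given number of phosphorothioate (sulfur) backbone modifications."""

    compound_id: str
    length: int
    sulfur_count: int
    true_tr: float  # minutes
    quality_tier: str

    def __post_init__(self):
        if self.length < 1:
            raise ParameterError("length must be >= 1")
        if not (0 <= self.sulfur_count <= self.length - 1):
            raise ParameterError("sulfur_count must lie in [0, length-1]")
        if self.true_tr <= 0:
            raise ParameterError("true_tr must be > 0")
        if self.quality_tier not in TIERS:
            raise ParameterError(f"quality_tier must be one of {TIERS}")


@dataclass(frozen=True)
class TierProfile:
    """Signal-quality parameter ranges for one latent tier.

    Low-quality runs have higher noise, stronger tailing, larger replicate
    retention-time jitter and (optionally) weaker signals — the qualitative
    signature of poor chromatography: low SNR, high skewness, unstable tR.
    """

    noise_sd_range: tuple  # intensity units
    tau_range: tuple  # minutes
    tr_jitter_sd: float  # minutes
    height_range: tuple  # intensity units
    sulfur_prob: float = 0.5  # per-position phosphorothioation probability
    length_range: tuple | None = None  # nucleotides; None = cohort default

    def __post_init__(self):
        for name in ("noise_sd_range", "tau_range", "height_range"):
            lo, hi = getattr(self, name)
            if lo < 0 or hi < lo:
                raise ParameterError(f"{name} must be a non-negative (lo, hi) pair")
        if self.tr_jitter_sd < 0:
            raise ParameterError("tr_jitter_sd must be >= 0")
        if not (0.0 <= self.sulfur_prob <= 1.0):
            raise ParameterError("sulfur_prob must lie in [0, 1]")
        if self.length_range is not None:
            lo, hi = self.length_range
            if lo < 1 or hi < lo:
                raise ParameterError("length_range must be a valid (lo, hi) pair")


#: Default tier profiles.  Noise, tailing and jitter ranges encode the
#: qualitative ordering that separates good from poor chromatography (low
#: tier strictly noisier and more tailing than high); heights encode that
#: higher-quality runs carry stronger signals.  Sequence composition is
#: tier-structured the way real quality strata are: high-quality compounds
#: are relatively long and lightly phosphorothioated, low-quality compounds
#: heavily phosphorothioated — heavily sulfur-modified oligonucleotides
#: produce noisier, more tailing signals.
DEFAULT_TIER_PROFILES = {
    "high": TierProfile(
        noise_sd_range=(0.5, 1.0),
        tau_range=(0.0, 0.02),
        tr_jitter_sd=0.005,
        height_range=(250.0, 450.0),
        sulfur_prob=0.1,
        length_range=(12, 20),
    ),
    "medium": TierProfile(
        noise_sd_range=(2.0, 5.0),
        tau_range=(0.05, 0.15),
        tr_jitter_sd=0.02,
        height_range=(60.0, 150.0),
        sulfur_prob=0.4,
        length_range=(5, 12),
    ),
    "low": TierProfile(
        noise_sd_range=(8.0, 15.0),
        tau_range=(0.2, 0.5),
        tr_jitter_sd=0.1,
        height_range=(150.0, 400.0),
        sulfur_prob=0.9,
        length_range=(12, 20),
    ),
}

#: Default run geometry: 0–25 min at 0.005 min sampling resolves half-height
#: crossings to well under 1% for sigma >= 0.05 min.
DEFAULT_GRID = (0.0, 25.0, 0.005)
DEFAULT_BASELINE = (2.0, 0.02)  # intercept, slope per minute
DEFAULT_SIGMA_RANGE = (0.04, 0.09)  # minutes
DEFAULT_LENGTH_RANGE = (5, 20)  # nucleotides, inclusive

#: Retention-time model: smooth increase with sequence length plus a
#: per-sulfur offset plus compound-level scatter, in minutes.
TR_INTERCEPT = 2.0
TR_PER_NUCLEOTIDE = 0.6
TR_PER_SULFUR = 0.22
TR_SCATTER_SD = 0.005


# ---------------------------------------------------------------------------
# signal model


def emg_profile(t, peak: PeakSpec):
    """Evaluate the peak profile P(t) at times ``t`` (minutes).

    For ``tau == 0`` this is the pure Gaussian
    ``height * exp(-(t - apex)^2 / (2 sigma^2))``.  For ``tau > 0`` it is the
    convolution of that Gaussian with a normalised one-sided exponential,
    evaluated through the numerically stable scaled-complementary-error-
    function (erfcx) formulation, so the total area is independent of tau.
    """
    t = np.asarray(t, dtype=float)
    h, mu, s, tau = peak.height, peak.apex_time, peak.sigma, peak.tau
    gauss = np.exp(-((t - mu) ** 2) / (2.0 * s * s))
    if tau < 1e-12 * s:
        return h * gauss
    z = (s / tau - (t - mu) / s) / _SQRT2
    scale = h * s / tau * _SQRT_HALF_PI
    out = np.empty_like(gauss)
    pos = z >= 0
    # z >= 0: erfcx absorbs the large positive exponent.
    out[pos] = scale * erfcx(z[pos]) * gauss[pos]
    # z < 0 (far tail): the plain exponent is strongly negative, so the
    # direct exp * erfc product is the stable branch.
    neg = ~pos
    if neg.any():
        a = 0.5 * (s / tau) ** 2 - (t[neg] - mu) / tau
        out[neg] = scale * np.exp(a) * erfc(z[neg])
    return out


def peak_area(peak: PeakSpec) -> float:
    """Analytic integrated area of a peak: height * sigma * sqrt(2*pi)."""
    return peak.height * peak.sigma * math.sqrt(2.0 * math.pi)


def render_chromatogram(run: RunSpec) -> Chromatogram:
    """Sample Y(t) = B(t) + sum of peaks + N(t) on the run's uniform grid.

    The same ``run.seed`` always reproduces the identical noise stream, so a
    fixed RunSpec renders bit-identically.
    """
    n = int(math.floor((run.time_end - run.time_start) / run.sampling_interval)) + 1
    t = run.time_start + np.arange(n) * run.sampling_interval
    signal = run.baseline_intercept + run.baseline_slope * t
    for peak in run.peaks:
        signal = signal + emg_profile(t, peak)
    rng = np.random.default_rng(run.seed)
    signal = signal + rng.normal(0.0, run.noise_sd, size=n)
    return Chromatogram(t, signal, meta={"seed": run.seed, "noise_sd": run.noise_sd})


def noise_free_signal(run: RunSpec):
    """Baseline plus analytic peak sum on the run's grid (no noise term)."""
    n = int(math.floor((run.time_end - run.time_start) / run.sampling_interval)) + 1
    t = run.time_start + np.arange(n) * run.sampling_interval
    signal = run.baseline_intercept + run.baseline_slope * t
    for peak in run.peaks:
        signal = signal + emg_profile(t, peak)
    return t, signal


# ---------------------------------------------------------------------------
# replicate pairs and cohorts


def _child_seed(seq: np.random.SeedSequence) -> int:
    # 31-bit integer seed for a RunSpec, derived deterministically.
    return int(seq.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


def simulate_replicate_pair(
    compound: CompoundSpec,
    tier: TierProfile,
    seed: int,
    *,
    grid: tuple = DEFAULT_GRID,
    baseline: tuple = DEFAULT_BASELINE,
    sigma_range: tuple = DEFAULT_SIGMA_RANGE,
):
    """Simulate the two replicate injections of one compound.

    Both runs share the drawn peak shape (height, sigma, tau) and noise
    level; the second run's apex time is the first plus Gaussian jitter with
    sd ``tier.tr_jitter_sd``, emulating run-to-run retention-time drift.

    Returns ``(chrom1, chrom2, truth)`` where ``truth`` is a dict holding the
    injected ground-truth parameters.
    """
    ss = np.random.SeedSequence(seed)
    params_ss, run1_ss, run2_ss = ss.spawn(3)
    rng = np.random.default_rng(params_ss)
    noise_sd = rng.uniform(*tier.noise_sd_range)
    tau = rng.uniform(*tier.tau_range)
    height = rng.uniform(*tier.height_range)
    sigma = rng.uniform(*sigma_range)
    jitter = rng.normal(0.0, tier.tr_jitter_sd) if tier.tr_jitter_sd > 0 else 0.0

    tr1 = compound.true_tr
    tr2 = compound.true_tr + jitter
    t0, t1, dt = grid
    intercept, slope = baseline
    chroms = []
    for tr, run_ss in ((tr1, run1_ss), (tr2, run2_ss)):
        peak = PeakSpec(compound.compound_id, tr, height, sigma, tau)
        run = RunSpec(
            time_start=t0,
            time_end=t1,
            sampling_interval=dt,
            peaks=(peak,),
            baseline_intercept=intercept,
            baseline_slope=slope,
            noise_sd=noise_sd,
            seed=_child_seed(run_ss),
        )
        chroms.append(render_chromatogram(run))
    truth = {
        "compound_id": compound.compound_id,
        "length": compound.length,
        "sulfur_count": compound.sulfur_count,
        "tier": compound.quality_tier,
        "true_tr_run1": tr1,
        "true_tr_run2": tr2,
        "noise_sd": noise_sd,
        "tau": tau,
        "height": height,
        "sigma": sigma,
    }
    return chroms[0], chroms[1], truth


@dataclass
class Cohort:
    """A simulated experiment: replicate chromatogram pairs plus the ground
    truth table (one row per compound, tier labels included)."""

    pairs: list  # list of (Chromatogram, Chromatogram)
    truth: pd.DataFrame

    def write_truth_csv(self, path) -> None:
        self.truth[TRUTH_COLUMNS].to_csv(
            path, index=False, float_format=CSV_FLOAT_FORMAT
        )


def _tier_counts(n: int, mixture: Sequence[float]) -> list:
    """Largest-remainder apportionment of n compounds over the tier mixture."""
    raw = [n * p for p in mixture]
    counts = [int(math.floor(r)) for r in raw]
    remainder = n - sum(counts)
    order = sorted(range(len(raw)), key=lambda i: raw[i] - counts[i], reverse=True)
    for i in order[:remainder]:
        counts[i] += 1
    return counts


def true_retention_time(length: int, sulfur_count: int, scatter: float = 0.0) -> float:
    """Retention-time model: linear in length and sulfur count plus scatter."""
    return TR_INTERCEPT + TR_PER_NUCLEOTIDE * length + TR_PER_SULFUR * sulfur_count + scatter


def simulate_cohort(
    n_compounds: int,
    tier_mixture: Sequence[float] = (1 / 3, 1 / 3, 1 / 3),
    tier_profiles: dict | None = None,
    seed: int = 0,
    *,
    length_range: tuple = DEFAULT_LENGTH_RANGE,
    grid: tuple = DEFAULT_GRID,
    baseline: tuple = DEFAULT_BASELINE,
    sigma_range: tuple = DEFAULT_SIGMA_RANGE,
) -> Cohort:
    """Simulate a cohort of compounds with latent quality tiers.

    ``tier_mixture`` gives the (high, medium, low) proportions and must sum
    to 1.  Tier counts are apportioned deterministically (largest remainder)
    and assigned to compounds in a seed-reproducible random order.  Lengths
    are uniform over ``length_range``; sulfur counts are binomial on
    ``length - 1`` positions with the tier's modification probability.
    """
    if n_compounds < 1:
        raise ParameterError("n_compounds must be >= 1")
    mixture = [float(p) for p in tier_mixture]
    if len(mixture) != len(TIERS):
        raise ParameterError(f"tier_mixture must have {len(TIERS)} entries")
    if any(p < 0 for p in mixture) or abs(sum(mixture) - 1.0) > 1e-9:
        raise ParameterError("tier_mixture must be non-negative and sum to 1")
    profiles = dict(DEFAULT_TIER_PROFILES if tier_profiles is None else tier_profiles)

    ss = np.random.SeedSequence(seed)
    cohort_ss = ss.spawn(1)[0]
    rng = np.random.default_rng(cohort_ss)

    counts = _tier_counts(n_compounds, mixture)
    tier_labels = np.repeat(TIERS, counts)
    tier_labels = tier_labels[rng.permutation(n_compounds)]

    pairs = []
    truth_rows = []
    # One spawned seed stream per compound keeps cohorts reproducible
    # element-wise: compound i's pair depends only on (seed, i).
    compound_seeds = ss.spawn(n_compounds)
    for i in range(n_compounds):
        tier_name = str(tier_labels[i])
        profile = profiles[tier_name]
        lo, hi = profile.length_range if profile.length_range is not None else length_range
        length = int(rng.integers(lo, hi + 1))
        sulfur = int(rng.binomial(length - 1, profile.sulfur_prob))
        tr = true_retention_time(length, sulfur, rng.normal(0.0, TR_SCATTER_SD))
        compound = CompoundSpec(
            compound_id=f"C{i:04d}",
            length=length,
            sulfur_count=sulfur,
            true_tr=float(np.clip(tr, 3.0, grid[1] - 3.0)),
            quality_tier=tier_name,
        )
        c1, c2, truth = simulate_replicate_pair(
            compound,
            profile,
            _child_seed(compound_seeds[i]),
            grid=grid,
            baseline=baseline,
            sigma_range=sigma_range,
        )
        pairs.append((c1, c2))
        truth_rows.append(truth)
    return Cohort(pairs=pairs, truth=pd.DataFrame(truth_rows))
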