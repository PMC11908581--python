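import numpy as np
import pytest
from hypothesis import settings

from chromqc.chromatogram import Chromatogram
from chromqc.simulate import PeakSpec, RunSpec, render_chromatogram

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def make_peak_chrom(
    apex=10.0,
    height=100.0,
    sigma=0.1,
    tau=0.0,
    noise_sd=0.0,
    intercept=0.0,
    slope=0.0,
    seed=0,
    grid=(0.0, 25.0, 0.005),
) -> Chromatogram:
    """Render a single-peak chromatogram for measurement tests."""
    run = RunSpec(
        time_start=grid[0],
        time_end=grid[1],
        sampling_interval=grid[2],
        peaks=(PeakSpec("p", apex, height, sigma, tau),),
        baseline_intercept=intercept,
        baseline_slope=slope,
        noise_sd=noise_sd,
        seed=seed,
    )
    return render_chromatogram(run)


def mirror_chrom(chrom: Chromatogram) -> Chromatogram:
    """Reverse the time axis (the mirrored peak fronts where it tailed)."""
    t0, t1 = chrom.time[0], chrom.time[-1]
    return Chromatogram((t0 + t1) - chrom.time[::-1], chrom.intensity[::-1])


@pytest.fixture
def peak_chrom_factory():
    return make_peak_chrom
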