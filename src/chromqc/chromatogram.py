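"""Chromatogram container: a detector signal sampled on a uniform time grid.

The detector trace Y(t) is modelled throughout the package as the sum of a
baseline B(t), one or more peaks P(t) and stochastic noise N(t).  This module
only carries the sampled signal; decomposition into those components is the
job of :mod:`chromqc.metrics` (measurement) and :mod:`chromqc.simulate`
(generation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError

MIN_POINTS = 16

#: float format used for every CSV the package writes, chosen so that a
#: write/read round trip reproduces the array bit-for-bit for doubles that
#: arise in practice (12 significant digits).
CSV_FLOAT_FORMAT = "%.12g"


@dataclass(frozen=True)
class Chromatogram:
    """A sampled chromatographic signal.

    Parameters
    ----------
    time : ndarray
        Sample times in minutes; strictly increasing, uniformly spaced.
    intensity : ndarray
        Detector intensity at each sample time, arbitrary detector units.
    """

    time: np.ndarray
    intensity: np.ndarray
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        time = np.asarray(self.time, dtype=float)
        intensity = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "intensity", intensity)
        if time.ndim != 1 or intensity.ndim != 1:
            raise ParameterError("time and intensity must be 1-D arrays")
        if len(time) != len(intensity):
            raise ParameterError("time and intensity must have equal length")
        if len(time) < MIN_POINTS:
            raise ParameterError(
                f"chromatogram needs at least {MIN_POINTS} points, got {len(time)}"
            )
        if not (np.isfinite(time).all() and np.isfinite(intensity).all()):
            raise ParameterError("chromatogram contains non-finite values")
        dt = np.diff(time)
        if not (dt > 0).all():
            raise ParameterError("time grid must be strictly increasing")

    @property
    def sampling_interval(self) -> float:
        return float(self.time[1] - self.time[0])

    def __len__(self) -> int:
        return len(self.time)

    def to_csv(self, path) -> None:
        """Write as the two-column dialect ``time_min,intensity``."""
        df = pd.DataFrame({"time_min": self.time, "intensity": self.intensity})
        df.to_csv(path, index=False, float_format=CSV_FLOAT_FORMAT)

    @classmethod
    def from_csv(cls, path) -> "Chromatogram":
        df = pd.read_csv(path)
        missing = {"time_min", "intensity"} - set(df.columns)
        if missing:
            raise ParameterError(f"chromatogram CSV missing columns: {sorted(missing)}")
        return cls(df["time_min"].to_numpy(float), df["intensity"].to_numpy(float))
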