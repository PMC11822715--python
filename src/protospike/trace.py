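"""The universal signal carrier: a time-stamped voltage series.

All pipeline stages exchange :class:`VoltageTrace` objects.  Times are in
seconds, potentials in millivolts; mixed-unit figures (ms traces for the
neuron model, multi-day recordings in seconds) are converted at the module
boundary, never inside an algorithm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class VoltageTrace:
    """A sampled electrical-potential series.

    Parameters
    ----------
    time : ndarray
        Sample times in seconds, non-decreasing.
    potential : ndarray
        Potential at each sample, millivolts.
    """

    time: np.ndarray
    potential: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.time, dtype=float)
        v = np.asarray(self.potential, dtype=float)
        if t.ndim != 1 or v.ndim != 1 or t.size != v.size:
            raise ValueError("time and potential must be 1-D arrays of equal length")
        if t.size == 0:
            raise ValueError("empty trace")
        if np.any(np.diff(t) < 0):
            raise ValueError("time must be non-decreasing")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "potential", v)

    def __len__(self):
        return self.time.size

    @property
    def duration(self) -> float:
        """Span of the recording in seconds."""
        return float(self.time[-1] - self.time[0])

    @property
    def sample_interval(self) -> float:
        """Median sampling step in seconds."""
        if len(self) < 2:
            raise ValueError("sample interval undefined for a single sample")
        return float(np.median(np.diff(self.time)))

    def is_uniform(self, rtol: float = 1e-6) -> bool:
        """Whether the trace is uniformly sampled to relative tolerance."""
        if len(self) < 3:
            return True
        d = np.diff(self.time)
        return bool(np.all(np.abs(d - d.mean()) <= rtol * abs(d.mean()) + 1e-15))


@dataclass(frozen=True)
class SpectrumCurve:
    """A per-frequency magnitude summary (Hz, dB)."""

    frequency: np.ndarray
    magnitude_db: np.ndarray

    def __post_init__(self):
        f = np.asarray(self.frequency, dtype=float)
        m = np.asarray(self.magnitude_db, dtype=float)
        if f.ndim != 1 or f.size != m.size:
            raise ValueError("frequency and magnitude_db must be 1-D, equal length")
        if f.size == 0:
            raise ValueError("empty spectrum curve")
        object.__setattr__(self, "frequency", f)
        object.__setattr__(self, "magnitude_db", m)

    def __len__(self):
        return self.frequency.size
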