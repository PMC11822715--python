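"""Spike detection and amplitude/period statistics.

Potential spikes are local maxima whose excursion above baseline reaches
a threshold (0.1 mV default) with a minimum separation between peaks
(50 ms default); when two candidates conflict the larger is kept.  The
summary statistics mirror the study's reporting: quartiles, mean,
extremes and sample standard deviation of spike amplitude and of the
inter-spike period (successive time differences — the first spike
contributes no period).  Quartiles use linear interpolation between
closest ranks; the baseline is a fixed reference (0 mV) by default with
an optional running-median alternative for drifting records.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter
from scipy.signal import find_peaks

from .trace import VoltageTrace


@dataclass(frozen=True)
class DetectorConfig:
    """Peak-detection settings.

    threshold : mV excursion above baseline; min_distance : s between
    retained peaks; baseline_mode : "fixed" (constant ``baseline``) or
    "median" (running median over ``median_window`` samples, odd).
    """

    threshold: float = 0.1
    min_distance: float = 0.05
    baseline_mode: str = "fixed"
    baseline: float = 0.0
    median_window: int = 601

    def __post_init__(self):
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if self.min_distance < 0:
            raise ValueError("min_distance must be non-negative")
        if self.baseline_mode not in ("fixed", "median"):
            raise ValueError("baseline_mode must be 'fixed' or 'median'")


@dataclass(frozen=True)
class SpikeTrain:
    """Detected peaks: times (s) and baseline-referenced amplitudes (mV)."""

    times: np.ndarray
    amplitudes: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        a = np.asarray(self.amplitudes, dtype=float)
        if t.size != a.size:
            raise ValueError("times and amplitudes must have equal length")
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("spike times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "amplitudes", a)

    def __len__(self):
        return self.times.size

    @property
    def periods(self) -> np.ndarray:
        """Inter-spike intervals in seconds (length n-1)."""
        return np.diff(self.times)


@dataclass(frozen=True)
class MetricStats:
    """Order statistics and moments of one metric."""

    q1: float
    median: float
    q3: float
    mean: float
    min: float
    max: float
    sd: float
    n: int

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("q1", "median", "q3", "mean", "min", "max", "sd", "n")}


@dataclass(frozen=True)
class SpikeStats:
    """Amplitude and period summaries; period is None below 2 spikes."""

    amplitude: MetricStats
    period: MetricStats | None
    n_spikes: int


def _metric_stats(x: np.ndarray) -> MetricStats:
    x = np.asarray(x, dtype=float)
    q1, med, q3 = np.quantile(x, [0.25, 0.5, 0.75])  # linear interpolation
    sd = float(np.std(x, ddof=1)) if x.size > 1 else float("nan")
    return MetricStats(float(q1), float(med), float(q3), float(x.mean()),
                       float(x.min()), float(x.max()), sd, int(x.size))


def detect_spikes(trace: VoltageTrace, cfg: DetectorConfig | None = None) -> SpikeTrain:
    """Find potential spikes in a trace.

    Local maxima with (value - baseline) >= threshold, any two retained
    peaks at least ``min_distance`` seconds apart (larger amplitude wins
    a conflict).  The trace must be time-sorted with >= 2 samples.
    """
    cfg = cfg or DetectorConfig()
    if len(trace) < 2:
        raise ValueError("trace must contain at least 2 samples")
    v = trace.potential
    if cfg.baseline_mode == "fixed":
        baseline = cfg.baseline
        excess = v - baseline
    else:
        win = cfg.median_window | 1  # force odd
        baseline = median_filter(v, size=win, mode="nearest")
        excess = v - baseline
    dt = trace.sample_interval
    distance = max(int(round(cfg.min_distance / dt)), 1)
    peaks, props = find_peaks(excess, height=cfg.threshold, distance=distance)
    return SpikeTrain(trace.time[peaks], props["peak_heights"])


def spike_statistics(train: SpikeTrain) -> SpikeStats:
    """Summary statistics of a detected spike train.

    Period statistics need >= 2 spikes; below that they are reported as
    absent (None), never as zero.
    """
    if len(train) == 0:
        raise ValueError("empty spike train has no statistics")
    amp = _metric_stats(train.amplitudes)
    per = _metric_stats(train.periods) if len(train) >= 2 else None
    return SpikeStats(amplitude=amp, period=per, n_spikes=len(train))


def dose_comparison(stats_by_dose: Mapping[float, SpikeStats] | list) -> pd.DataFrame:
    """Tabulate mean amplitude and mean period against concentration.

    Accepts a mapping {concentration (mg/mL): SpikeStats} or a list of
    (concentration, SpikeStats) pairs; duplicate concentrations are an
    error.  Returns a DataFrame sorted by concentration.
    """
    items = list(stats_by_dose.items()) if isinstance(stats_by_dose, Mapping) \
        else list(stats_by_dose)
    if not items:
        raise ValueError("need at least one dose")
    concs = [c for c, _ in items]
    if len(set(concs)) != len(concs):
        raise ValueError("duplicate concentration keys")
    rows = [
        {
            "concentration_mg_per_mL": float(c),
            "mean_amplitude_mV": s.amplitude.mean,
            "mean_period_s": s.period.mean if s.period is not None else float("nan"),
            "n_spikes": s.n_spikes,
        }
        for c, s in items
    ]
    return (pd.DataFrame(rows)
            .sort_values("concentration_mg_per_mL")
            .reset_index(drop=True))
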