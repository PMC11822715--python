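"""Persistence spectrum and power-law exponent estimation.

The persistence (time-occupancy) spectrum histograms short-time power
spectra: for each frequency it records how often the magnitude fell in
each decibel bin across analysis windows, exposing how persistent each
spectral feature is.  A per-frequency summary curve (modal magnitude by
default) is then fitted with the three-parameter logarithm

    y = a - b ln(x + c)        [y in dB, x in Hz]

whose slope coefficient b encodes the power-law character of the
background: the spectral exponent is reported as beta = -b.  For a
1/f^beta background expressed in natural-log power units the fitted b
equals the generator's beta, so the pipeline helper converts dB to
ln-power (x ln10 / 10) before fitting when estimating the exponent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import lmfit
from scipy.signal import spectrogram

from .errors import FitFailureError
from .fitting import GoodnessOfFit, goodness_of_fit
from .spikes import MetricStats, _metric_stats
from .trace import SpectrumCurve, VoltageTrace

DB_FLOOR = -150.0  # dB floor so silent bins stay finite


@dataclass(frozen=True)
class PersistenceMap:
    """Occupancy histogram of short-time spectra.

    frequency : Hz (n_freq,); magnitude_bins : dB bin centres (n_bins,);
    occupancy : (n_freq, n_bins), each frequency row sums to 1.
    """

    frequency: np.ndarray
    magnitude_bins: np.ndarray
    occupancy: np.ndarray

    def __post_init__(self):
        occ = np.asarray(self.occupancy, dtype=float)
        sums = occ.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("occupancy must sum to 1 per frequency row")
        object.__setattr__(self, "frequency", np.asarray(self.frequency, dtype=float))
        object.__setattr__(self, "magnitude_bins", np.asarray(self.magnitude_bins, dtype=float))
        object.__setattr__(self, "occupancy", occ)


def persistence_spectrum(trace: VoltageTrace, window_length: int = 1024,
                         overlap: float = 0.5, bin_width_db: float = 1.0,
                         summary: str = "modal"):
    """Persistence spectrum of a uniformly sampled trace.

    Hann-windowed short-time power spectral densities (dB, 10*log10)
    are histogrammed per frequency into ``bin_width_db`` bins.  The
    summary curve per frequency is the modal-occupancy bin centre
    ("modal", default), the maximum observed magnitude ("max") or the
    mean magnitude ("mean").

    Returns (PersistenceMap, SpectrumCurve).
    """
    if not trace.is_uniform():
        raise ValueError("trace must be uniformly sampled; resample upstream")
    n = len(trace)
    if window_length >= n:
        raise ValueError("window_length must be shorter than the trace")
    if not 0 <= overlap < 1:
        raise ValueError("overlap must lie in [0, 1)")
    if summary not in ("modal", "max", "mean"):
        raise ValueError(f"unknown summary {summary!r}")
    fs = 1.0 / trace.sample_interval
    freqs, _, sxx = spectrogram(trace.potential, fs=fs, window="hann",
                                nperseg=window_length,
                                noverlap=int(overlap * window_length),
                                detrend=False, scaling="density", mode="psd")
    with np.errstate(divide="ignore"):
        db = 10.0 * np.log10(sxx)
    db = np.maximum(db, DB_FLOOR)

    lo = DB_FLOOR
    hi = float(db.max()) + bin_width_db
    edges = np.arange(lo, hi + bin_width_db, bin_width_db)
    centres = (edges[:-1] + edges[1:]) / 2.0
    occ = np.empty((freqs.size, centres.size))
    for i in range(freqs.size):
        counts, _ = np.histogram(db[i], bins=edges)
        occ[i] = counts / counts.sum()
    pmap = PersistenceMap(freqs, centres, occ)

    if summary == "modal":
        mag = centres[np.argmax(occ, axis=1)]
    elif summary == "max":
        mag = db.max(axis=1)
    else:
        mag = db.mean(axis=1)
    return pmap, SpectrumCurve(freqs, mag)


@dataclass(frozen=True)
class Log3P1Fit:
    """Fitted y = a - b ln(x + c) with per-parameter standard errors."""

    a: float
    b: float
    c: float
    stderr: dict
    gof: GoodnessOfFit

    @property
    def reduced_chi2(self) -> float:
        return self.gof.reduced_chi2

    @property
    def r2(self) -> float:
        return self.gof.r2


def fit_log3p1(curve: SpectrumCurve, init: tuple | None = None,
               vary_c: bool = True) -> Log3P1Fit:
    """Nonlinear least-squares fit of y = a - b ln(x + c), c >= 0.

    ``init`` is an optional (a, b, c) triple; otherwise b and a are
    seeded from a straight-line fit of y against ln(x + c0).  Requires
    at least 4 points with x + c > 0 across the search domain.
    """
    if len(curve) < 4:
        raise ValueError("need at least 4 points")
    x, y = curve.frequency, curve.magnitude_db

    def model(x, a, b, c):
        return a - b * np.log(x + c)

    if init is None:
        c0 = max(1e-12, -float(x.min()) + 1e-12) if x.min() <= 0 else 0.0
        c0 = c0 or min(1e-6, float(x[x > 0].min()) / 10)
        lx = np.log(x + c0)
        slope, intercept = np.polyfit(lx, y, 1)
        init = (float(intercept), float(-slope), c0)
    a0, b0, c0 = init
    if np.any(x + c0 <= 0):
        raise ValueError("x + c must be positive over the search domain")
    m = lmfit.Model(model)
    pars = m.make_params(a=a0, b=b0, c=max(c0, 0.0))
    pars["c"].set(min=0.0, vary=vary_c)
    # keep ln(x+c) defined: c may shrink to 0 only if all x > 0
    if x.min() <= 0:
        pars["c"].set(min=1e-15)
    try:
        res = m.fit(y, pars, x=x)
    except Exception as exc:
        raise FitFailureError(f"Log3P1 fit failed: {exc}") from exc
    if not res.success:
        raise FitFailureError("Log3P1 fit did not converge",
                              diagnostics={"message": res.message})
    stderr = {k: (float(res.params[k].stderr) if res.params[k].stderr is not None else np.nan)
              for k in ("a", "b", "c")}
    n_par = 3 if vary_c else 2
    return Log3P1Fit(float(res.params["a"].value), float(res.params["b"].value),
                     float(res.params["c"].value), stderr,
                     goodness_of_fit(y, res.best_fit, n_par))


def power_law_exponent(fit: Log3P1Fit) -> float:
    """Spectral power-law exponent beta = -b of a converged fit."""
    return -fit.b


def magnitude_summary(curve: SpectrumCurve) -> MetricStats:
    """Moments and quartiles (dB) of a summary curve's magnitudes."""
    if len(curve) == 0:
        raise ValueError("empty curve")
    return _metric_stats(curve.magnitude_db)


def persistent_spectrum_exponent(trace: VoltageTrace, window_length: int = 1024,
                                 overlap: float = 0.5, summary: str = "mean") -> float:
    """End-to-end spectral exponent of a recording.

    Computes the persistence spectrum, converts the summary magnitudes
    from dB to natural-log power units (x ln10 / 10) so the logarithmic
    slope coefficient is the power-law exponent itself, fits
    y = a - b ln(x) (c pinned at 0; the zero-frequency row is dropped)
    and returns -b.  A 1/f background yields approximately -1.
    """
    _, curve = persistence_spectrum(trace, window_length=window_length,
                                    overlap=overlap, summary=summary)
    keep = curve.frequency > 0
    y_ln = curve.magnitude_db[keep] * (np.log(10.0) / 10.0)
    sub = SpectrumCurve(curve.frequency[keep], y_ln)
    lx = np.log(sub.frequency)
    slope, intercept = np.polyfit(lx, y_ln, 1)
    fit = fit_log3p1(sub, init=(float(intercept), float(-slope), 0.0), vary_c=False)
    return power_law_exponent(fit)
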