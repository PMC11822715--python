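"""Dielectric relaxation analysis of capacitance spectra.

A capacitance-versus-frequency spectrum measured between two needle
electrodes is (i) converted to relative permittivity from the cell
geometry, (ii) fitted with a four-parameter logistic dispersion curve,
and (iii) mapped onto single-relaxation-time (Debye) parameters: the
static permittivity is the low-frequency plateau, the high-frequency
permittivity the upper plateau, and the relaxation time follows from
the logistic midpoint frequency, tau = 1/(2*pi*x0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import lmfit

from .errors import FitFailureError
from .fitting import GoodnessOfFit, goodness_of_fit

VACUUM_PERMITTIVITY = 8.85418782e-12  # F/m


@dataclass(frozen=True)
class CellGeometry:
    """Parallel-needle measurement cell.

    electrode_separation : m, distance between the electrodes.
    electrode_thickness : m, diameter of the needle electrodes; the
        effective electrode area is the disc pi*(thickness/2)^2.
    """

    electrode_separation: float = 0.01
    electrode_thickness: float = 0.002
    vacuum_permittivity: float = VACUUM_PERMITTIVITY

    def __post_init__(self):
        if self.electrode_separation <= 0 or self.electrode_thickness <= 0:
            raise ValueError("geometry lengths must be positive")

    @property
    def area(self) -> float:
        """Electrode area in m^2 (computed, never stored)."""
        return float(np.pi * (self.electrode_thickness / 2.0) ** 2)


@dataclass(frozen=True)
class LogisticParams:
    """Four-parameter logistic capacitance dispersion.

    A1 : F, low-frequency plateau.  A2 : F, high-frequency plateau.
    x0 : Hz, midpoint frequency.  p : shape exponent.
    """

    A1: float
    A2: float
    x0: float
    p: float

    def __post_init__(self):
        if self.x0 <= 0:
            raise ValueError("x0 must be positive")
        if self.p == 0:
            raise ValueError("p must be nonzero")


@dataclass(frozen=True)
class DebyeParams:
    """Single-relaxation-time dispersion parameters.

    eps_s and eps_inf are stored exactly as assigned from the logistic
    plateaus (the measurement reports them in F/m); tau in seconds.
    """

    eps_s: float
    eps_inf: float
    tau: float

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("tau must be positive")


@dataclass(frozen=True)
class CapacitanceSpectrum:
    """Capacitance (F) sampled on a positive, increasing frequency grid (Hz)."""

    frequency: np.ndarray
    capacitance: np.ndarray

    def __post_init__(self):
        f = np.asarray(self.frequency, dtype=float)
        c = np.asarray(self.capacitance, dtype=float)
        if f.ndim != 1 or f.size != c.size:
            raise ValueError("frequency and capacitance must be 1-D, equal length")
        if f.size == 0:
            raise ValueError("empty spectrum")
        if np.any(f <= 0):
            raise ValueError("frequencies must be positive")
        if np.any(np.diff(f) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        object.__setattr__(self, "frequency", f)
        object.__setattr__(self, "capacitance", c)

    def __len__(self):
        return self.frequency.size


def relative_permittivity(capacitance, geometry: CellGeometry | None = None):
    """Relative permittivity eps_r = C * d / (eps0 * A) of a measured capacitance.

    Accepts a scalar or array of capacitances in Farads; dimensionless result.
    """
    geometry = geometry or CellGeometry()
    c = np.asarray(capacitance, dtype=float)
    if np.any(c < 0):
        raise ValueError("capacitance must be non-negative")
    out = c * geometry.electrode_separation / (geometry.vacuum_permittivity * geometry.area)
    return float(out) if np.isscalar(capacitance) else out


def logistic_capacitance(params: LogisticParams, frequency):
    """Evaluate C(f) = A2 + (A1 - A2) / (1 + (f/x0)^p)."""
    f = np.asarray(frequency, dtype=float)
    if np.any(f <= 0):
        raise ValueError("frequency must be positive")
    out = params.A2 + (params.A1 - params.A2) / (1.0 + (f / params.x0) ** params.p)
    return float(out) if np.isscalar(frequency) else out


@dataclass(frozen=True)
class LogisticFit:
    params: LogisticParams
    stderr: dict
    gof: GoodnessOfFit


def fit_logistic(spectrum: CapacitanceSpectrum, init: LogisticParams | None = None,
                 weighting: str = "uniform") -> LogisticFit:
    """Least-squares fit of the four-parameter logistic dispersion.

    Requires at least 5 points spanning the transition.  ``weighting``
    is "uniform" (absolute residuals, the default) or "proportional"
    (residuals scaled by 1/|C|, the appropriate choice when the noise
    is multiplicative).  A negative fitted high-frequency plateau is
    permitted (a known limitation of the logistic form at high
    frequency) but triggers a warning.
    """
    if len(spectrum) < 5:
        raise ValueError("need at least 5 points to fit the logistic model")
    if weighting not in ("uniform", "proportional"):
        raise ValueError(f"unknown weighting {weighting!r}")
    f, c = spectrum.frequency, spectrum.capacitance

    def model(x, A1, A2, x0, p):
        return A2 + (A1 - A2) / (1.0 + (x / x0) ** p)

    m = lmfit.Model(model)
    if init is None:
        # plateau guesses from the grid ends; midpoint where C crosses halfway
        a1, a2 = float(c[0]), float(c[-1])
        half = (a1 + a2) / 2.0
        idx = int(np.argmin(np.abs(c - half)))
        init = LogisticParams(A1=a1, A2=a2, x0=max(float(f[idx]), f[0]), p=1.0)
    pars = m.make_params(A1=init.A1, A2=init.A2, x0=init.x0, p=init.p)
    pars["x0"].set(min=np.finfo(float).tiny)
    weights = None
    if weighting == "proportional":
        weights = 1.0 / np.maximum(np.abs(c), np.finfo(float).tiny)
    try:
        res = m.fit(c, pars, x=f, weights=weights)
    except Exception as exc:  # pragma: no cover - lmfit internal failures
        raise FitFailureError(f"logistic fit failed: {exc}") from exc
    if not res.success:
        raise FitFailureError("logistic fit did not converge",
                              diagnostics={"message": res.message})
    fitted = LogisticParams(**{k: float(res.params[k].value) for k in ("A1", "A2", "x0", "p")})
    if fitted.A2 < 0:
        warnings.warn("fitted high-frequency plateau A2 is negative; the logistic "
                      "form does not capture the high-frequency limit", stacklevel=2)
    stderr = {k: (float(res.params[k].stderr) if res.params[k].stderr is not None else np.nan)
              for k in ("A1", "A2", "x0", "p")}
    return LogisticFit(fitted, stderr, goodness_of_fit(c, res.best_fit, 4))


def debye_from_logistic(params: LogisticParams) -> DebyeParams:
    """Map logistic fit parameters to Debye parameters.

    eps_s = A1, eps_inf = A2 (plateau identification) and
    tau = 1/(2*pi*x0) from the midpoint frequency.
    """
    if params.x0 <= 0:
        raise ValueError("x0 must be positive")
    return DebyeParams(eps_s=params.A1, eps_inf=params.A2,
                       tau=1.0 / (2.0 * np.pi * params.x0))


def debye_permittivity(dp: DebyeParams, omega):
    """Complex permittivity eps* = eps_inf + (eps_s - eps_inf) / (1 + j*omega*tau).

    omega in rad/s (>= 0).  Physics sign convention: +j*omega*tau in the
    denominator, so the imaginary part is negative for eps_s > eps_inf.
    """
    w = np.asarray(omega, dtype=float)
    if np.any(w < 0):
        raise ValueError("omega must be non-negative")
    out = dp.eps_inf + (dp.eps_s - dp.eps_inf) / (1.0 + 1j * w * dp.tau)
    return complex(out) if np.isscalar(omega) else out
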