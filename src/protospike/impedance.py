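"""Impedance-spectroscopy models: empirical Exp3P2 and the Randles circuit.

Two complementary descriptions of an electrochemical interface:

* ``Z = exp(a + b*f + c*f^2)`` — a purely empirical magnitude model,
  linear in its parameters after taking logs, solved exactly by normal
  equations.
* The Randles equivalent circuit — a solution resistance Rs in series
  with a double-layer capacitance Cdl in parallel with the faradaic
  branch (charge-transfer resistance Rct plus a semi-infinite Warburg
  diffusion element W(w) = Zw * w^(-1/2) * (1 - j)).

The Randles fit uses complex least squares on jointly stacked real and
imaginary residuals, with log-scaled positive parameters, an analytic
Jacobian and (by default) component-wise proportional weighting.  The
analytic Jacobian matters: for strongly capacitor-dominated spectra the
faradaic parameters perturb Z only at the 1e-9 relative level, far below
what finite-difference derivatives can resolve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .errors import FitFailureError
from .fitting import GoodnessOfFit, goodness_of_fit

_EXP_OVERFLOW = 700.0  # exp argument beyond which float64 overflows


@dataclass(frozen=True)
class Exp3P2Params:
    """Exponential-quadratic magnitude model parameters.

    a : ln-ohm intercept; b : per-Hz; c : per-Hz^2.
    """

    a: float
    b: float
    c: float

    def __post_init__(self):
        if not all(np.isfinite([self.a, self.b, self.c])):
            raise ValueError("Exp3P2 parameters must be finite")


@dataclass(frozen=True)
class RandlesParams:
    """Randles equivalent-circuit element values (all non-negative).

    Rs : ohm solution resistance; Cdl : F double-layer capacitance;
    Rct : ohm charge-transfer resistance; Zw : ohm*s^(-1/2) Warburg
    coefficient.
    """

    Rs: float
    Cdl: float
    Rct: float
    Zw: float

    def __post_init__(self):
        if min(self.Rs, self.Cdl, self.Rct, self.Zw) < 0:
            raise ValueError("Randles parameters must be non-negative")


@dataclass(frozen=True)
class ImpedanceSpectrum:
    """Complex impedance on a positive, strictly increasing frequency grid."""

    frequency: np.ndarray
    Z: np.ndarray

    def __post_init__(self):
        f = np.asarray(self.frequency, dtype=float)
        z = np.asarray(self.Z, dtype=complex)
        if f.ndim != 1 or f.size != z.size:
            raise ValueError("frequency and Z must be 1-D, equal length")
        if f.size == 0:
            raise ValueError("empty spectrum")
        if np.any(f <= 0) or np.any(np.diff(f) <= 0):
            raise ValueError("frequencies must be positive and strictly increasing")
        object.__setattr__(self, "frequency", f)
        object.__setattr__(self, "Z", z)

    def __len__(self):
        return self.frequency.size


def exp3p2(params: Exp3P2Params, frequency):
    """Evaluate the magnitude model Z = exp(a + b*f + c*f^2) in ohms."""
    f = np.asarray(frequency, dtype=float)
    if np.any(f < 0):
        raise ValueError("frequency must be non-negative")
    arg = params.a + params.b * f + params.c * f**2
    if np.any(arg > _EXP_OVERFLOW):
        bad = np.atleast_1d(f)[np.atleast_1d(arg) > _EXP_OVERFLOW][0]
        raise OverflowError(f"Exp3P2 overflows at f = {bad} Hz")
    out = np.exp(arg)
    return float(out) if np.isscalar(frequency) else out


@dataclass(frozen=True)
class Exp3P2Fit:
    params: Exp3P2Params
    gof: GoodnessOfFit


def fit_exp3p2(frequency, magnitude) -> Exp3P2Fit:
    """Exact linear least-squares fit of ln|Z| = a + b*f + c*f^2.

    The design matrix [1, f, f^2] needs at least three distinct
    frequencies; otherwise the problem is rank deficient.
    """
    f = np.asarray(frequency, dtype=float)
    z = np.asarray(magnitude, dtype=float)
    if f.size != z.size or f.size < 4:
        raise ValueError("need at least 4 (frequency, |Z|) points")
    if np.any(z <= 0):
        raise ValueError("magnitudes must be positive to take logs")
    X = np.column_stack([np.ones_like(f), f, f**2])
    if np.linalg.matrix_rank(X) < 3:
        raise FitFailureError("rank-deficient design: need >= 3 distinct frequencies")
    y = np.log(z)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    params = Exp3P2Params(*map(float, coef))
    return Exp3P2Fit(params, goodness_of_fit(y, X @ coef, 3))


def randles_impedance(params: RandlesParams, frequency):
    """Complex impedance of the Randles circuit at frequency f (Hz, > 0).

    Z(w) = Rs + [j*w*Cdl + 1/(Rct + W(w))]^-1,
    W(w) = Zw * w^(-1/2) * (1 - j), w = 2*pi*f.
    """
    f = np.asarray(frequency, dtype=float)
    if np.any(f <= 0):
        raise ValueError("frequency must be positive")
    w = 2.0 * np.pi * f
    faradaic = params.Rct + params.Zw * w**-0.5 * (1.0 - 1.0j)
    with np.errstate(divide="ignore"):
        branch = np.where(
            np.abs(faradaic) > 0,
            1.0 / (1j * w * params.Cdl + 1.0 / np.where(np.abs(faradaic) > 0, faradaic, 1.0)),
            0.0,
        )
    out = params.Rs + branch
    return complex(out) if np.isscalar(frequency) else out


def nyquist(spectrum: ImpedanceSpectrum) -> np.ndarray:
    """Nyquist representation: (Re Z, -Im Z) pairs, order preserved."""
    return np.column_stack([spectrum.Z.real, -spectrum.Z.imag])


@dataclass(frozen=True)
class RandlesFit:
    params: RandlesParams
    stderr: dict
    gof: GoodnessOfFit
    cost: float


def _randles_model_jac(f: np.ndarray, p: np.ndarray):
    """Z(f) and dZ/dp (complex, columns Rs, Cdl, Rct, Zw) analytically."""
    Rs, Cdl, Rct, Zw = p
    w = 2.0 * np.pi * f
    s = w**-0.5 * (1.0 - 1.0j)
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        faradaic = Rct + Zw * s
        D = 1j * w * Cdl + 1.0 / faradaic
        Z = Rs + 1.0 / D
        invD2 = 1.0 / D**2
        dRs = np.ones_like(Z)
        dCdl = -invD2 * 1j * w
        dRct = invD2 / faradaic**2
        dZw = invD2 * s / faradaic**2
    return Z, np.stack([dRs, dCdl, dRct, dZw], axis=1)


def fit_randles(
    spectrum: ImpedanceSpectrum,
    init: RandlesParams | None = None,
    bounds: tuple | None = None,
    weighting: str = "proportional",
) -> RandlesFit:
    """Complex least-squares fit of the Randles circuit.

    Real and imaginary residuals are stacked; ``weighting`` selects the
    standard impedance-fitting schemes: "unit" (absolute residuals),
    "modulus" (each residual scaled by 1/|Z|) or "proportional" (real
    and imaginary parts each scaled by their own data component).
    Parameters are optimised in log space, which enforces positivity and
    equalises sensitivities across the many decades the circuit elements
    span.  Needs >= 8 points over >= 2 frequency decades.
    """
    f, Z = spectrum.frequency, spectrum.Z
    if len(spectrum) < 8:
        raise ValueError("need at least 8 spectrum points")
    if np.log10(f[-1] / f[0]) < 2.0:
        raise ValueError("spectrum must span at least 2 frequency decades")

    if weighting == "unit":
        wr = wi = np.ones_like(f)
    elif weighting == "modulus":
        wr = wi = 1.0 / np.maximum(np.abs(Z), np.finfo(float).tiny)
    elif weighting == "proportional":
        floor = 1e-12 * np.maximum(np.abs(Z), np.finfo(float).tiny)
        wr = 1.0 / np.maximum(np.abs(Z.real), floor)
        wi = 1.0 / np.maximum(np.abs(Z.imag), floor)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")

    # data-driven heuristic start: Rs from the high-frequency real limit,
    # Rct from the low-frequency increase, Cdl from the apex of -Im Z
    rs0 = max(float(Z.real[-1]), np.finfo(float).tiny)
    rct0 = max(float(Z.real[0] - Z.real[-1]), rs0)
    k = int(np.argmax(-Z.imag))
    cdl0 = 1.0 / (2.0 * np.pi * f[k] * rct0)
    zw0 = max(float(-Z.imag[0] * np.sqrt(2.0 * np.pi * f[0])), rs0)
    starts = [np.array([rs0, cdl0, rct0, zw0], dtype=float)]
    if init is not None:
        p0 = np.array([init.Rs, init.Cdl, init.Rct, init.Zw], dtype=float)
        if np.any(p0 <= 0):
            raise ValueError("initial Randles parameters must be positive for the "
                             "log-space fit")
        # multi-start: user init first, heuristic as a safeguard against
        # local minima in weakly identifiable spectra
        starts.insert(0, p0)
    if bounds is not None:
        lo = np.array([max(b, np.finfo(float).tiny) for b in bounds[0]], dtype=float)
        hi = np.array(bounds[1], dtype=float)
        log_bounds = (np.log(lo), np.log(hi))
    else:
        log_bounds = (-np.inf, np.inf)

    def resid(logp):
        Zm, _ = _randles_model_jac(f, np.exp(logp))
        return np.concatenate([(Zm.real - Z.real) * wr, (Zm.imag - Z.imag) * wi])

    def jac(logp):
        p = np.exp(logp)
        _, J = _randles_model_jac(f, p)
        J = J * p[None, :]  # chain rule: d/d(log p)
        return np.concatenate([J.real * wr[:, None], J.imag * wi[:, None]])

    res = None
    for p0 in starts:
        cand = least_squares(resid, np.log(p0), jac=jac, bounds=log_bounds,
                             xtol=1e-14, ftol=None, gtol=1e-14, max_nfev=5000)
        if res is None or cand.cost < res.cost:
            res = cand
    if not res.success and res.status <= 0:
        raise FitFailureError(
            "Randles fit did not converge",
            diagnostics={"best_params": np.exp(res.x).tolist(), "message": res.message},
        )
    p = np.exp(res.x)
    params = RandlesParams(*map(float, p))

    # standard errors via the Gauss-Newton covariance in log space
    J = jac(res.x)
    r = resid(res.x)
    dof = max(r.size - 4, 1)
    s2 = float(r @ r) / dof
    try:
        cov_log = np.linalg.inv(J.T @ J) * s2
        stderr_vals = p * np.sqrt(np.maximum(np.diag(cov_log), 0.0))
    except np.linalg.LinAlgError:
        stderr_vals = np.full(4, np.nan)
    stderr = dict(zip(("Rs", "Cdl", "Rct", "Zw"), map(float, stderr_vals)))

    Zm, _ = _randles_model_jac(f, p)
    y = np.concatenate([Z.real, Z.imag])
    ym = np.concatenate([Zm.real, Zm.imag])
    return RandlesFit(params, stderr, goodness_of_fit(y, ym, 4), float(res.cost))
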