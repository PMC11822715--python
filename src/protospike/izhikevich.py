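"""Thalamocortical Izhikevich neuron used to build stimulation waveforms.

The two-variable quadratic integrate-and-reset model

    dv/dt = 0.04 v^2 + 5 v + 140 - u + I
    du/dt = a (b v - u)

with the discontinuous reset ``v <- c, u <- u + d`` whenever the
membrane potential reaches the +30 mV spike peak.  The thalamocortical
parameter regime (a=0.02, b=0.25, c=-65, d=0.05) produces the
low-threshold spiking patterns used here as a stimulation channel for
proteinoid samples.  Integration is explicit Euler at dt = 0.1 ms, the
model's standard treatment; the sample at each threshold crossing is
emitted as exactly v_peak before the reset so plotted peaks are uniform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import IntegrationError
from .trace import VoltageTrace


@dataclass(frozen=True)
class IzhikevichParams:
    """Model parameters; defaults are the thalamocortical regime.

    a : recovery rate (1/ms); b : recovery sensitivity; c : reset
    potential (mV); d : recovery increment (mV); v_peak : spike cutoff (mV).
    """

    a: float = 0.02
    b: float = 0.25
    c: float = -65.0
    d: float = 0.05
    v_peak: float = 30.0

    def __post_init__(self):
        if self.a <= 0:
            raise ValueError("a must be positive")
        if self.v_peak <= self.c:
            raise ValueError("v_peak must exceed the reset potential c")

    def resting_state(self) -> tuple[float, float]:
        """Stable fixed point (v*, u*) of the subthreshold dynamics at I=0.

        Solves 0.04 v^2 + 5 v + 140 - b v = 0 and takes the more
        hyperpolarised root, which is the stable equilibrium.
        """
        disc = (5.0 - self.b) ** 2 - 4 * 0.04 * 140.0
        if disc < 0:
            raise ValueError("no real resting state for these parameters")
        v = (-(5.0 - self.b) - np.sqrt(disc)) / (2 * 0.04)
        return float(v), float(self.b * v)


@dataclass(frozen=True)
class IzhikevichResult:
    """Simulation output.

    t_ms : sample times (ms).  v : emitted membrane potential (mV),
    clipped at v_peak on spike samples.  v_state / u : the internal
    state *after* any reset at each sample, so the reset contract
    (v_state = c, u incremented by d) is directly inspectable.
    spike_times_ms : times at which the peak cutoff was reached.
    """

    t_ms: np.ndarray
    v: np.ndarray
    v_state: np.ndarray
    u: np.ndarray
    spike_times_ms: np.ndarray

    @property
    def n_spikes(self) -> int:
        return self.spike_times_ms.size

    def trace(self) -> VoltageTrace:
        """Emitted potential as a VoltageTrace (time converted to seconds)."""
        return VoltageTrace(self.t_ms / 1e3, self.v)


def _current_program(input_current, t_ms: np.ndarray) -> np.ndarray:
    """Resolve a current specification to per-sample values.

    Accepts a scalar (constant drive), an array matching the time grid,
    a callable I(t_ms), or a (times_ms, amps) pair with step-hold
    semantics (the value at each program time holds until the next).
    """
    if np.isscalar(input_current):
        return np.full(t_ms.size, float(input_current))
    if callable(input_current):
        return np.asarray([float(input_current(t)) for t in t_ms])
    if isinstance(input_current, tuple) and len(input_current) == 2:
        knots, amps = (np.asarray(a, dtype=float) for a in input_current)
        pos = np.clip(np.searchsorted(knots, t_ms, side="right") - 1, 0, knots.size - 1)
        out = amps[pos]
        out[t_ms < knots[0]] = 0.0
        return out
    arr = np.asarray(input_current, dtype=float)
    if arr.size != t_ms.size:
        raise ValueError("per-sample current array must match the time grid")
    return arr


def simulate(params: IzhikevichParams, input_current, dt: float = 0.1,
             duration: float = 1000.0, v0: float | None = None,
             u0: float | None = None) -> IzhikevichResult:
    """Forward-integrate the model with explicit Euler.

    dt and duration in ms.  Defaults start from the resting fixed point.
    Raises IntegrationError (with the failure time) if the state leaves
    the representable range.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if duration < dt:
        raise ValueError("duration must be at least dt")
    n = int(round(duration / dt)) + 1
    t = np.arange(n) * dt
    I = _current_program(input_current, t)

    if v0 is None or u0 is None:
        v_rest, u_rest = params.resting_state()
        v0 = v_rest if v0 is None else v0
        u0 = u_rest if u0 is None else u0

    v_emit = np.empty(n)
    v_state = np.empty(n)
    u_arr = np.empty(n)
    spikes = []
    v, u = float(v0), float(u0)
    v_emit[0] = v_state[0] = min(v, params.v_peak)
    u_arr[0] = u
    for k in range(1, n):
        dv = 0.04 * v * v + 5.0 * v + 140.0 - u + I[k - 1]
        du = params.a * (params.b * v - u)
        v_new = v + dt * dv
        u_new = u + dt * du
        if not (np.isfinite(v_new) and np.isfinite(u_new)):
            raise IntegrationError("non-finite state during integration",
                                   t_failure=float(t[k]))
        if v_new >= params.v_peak:
            v_emit[k] = params.v_peak
            spikes.append(t[k])
            v, u = params.c, u_new + params.d
        else:
            v_emit[k] = v_new
            v, u = v_new, u_new
        v_state[k] = v
        u_arr[k] = u
    return IzhikevichResult(t, v_emit, v_state, u_arr, np.asarray(spikes))


def tc_stimulus(params: IzhikevichParams, current_program, dt: float = 0.1,
                duration: float = 1000.0, gain: float = 0.1) -> VoltageTrace:
    """Stimulation waveform: the simulated trace rescaled by ``gain``.

    ``gain`` maps the model's mV scale onto the stimulation channel's
    (e.g. 0.1 turns +30 mV peaks into 3 mV pulses).
    """
    res = simulate(params, current_program, dt=dt, duration=duration)
    return VoltageTrace(res.t_ms / 1e3, res.v * gain)


def response_emulator(stimulus: VoltageTrace, coupling_tau: float,
                      noise_rms: float = 0.0, offset: float = 0.0,
                      seed: int = 0) -> VoltageTrace:
    """First-order (RC) response to a stimulation waveform.

    A stand-in for the physical sample response: the stimulus low-pass
    filtered with time constant ``coupling_tau`` (seconds), plus an
    optional DC offset and white noise.  As coupling_tau -> 0 the output
    approaches the stimulus itself.
    """
    if coupling_tau <= 0:
        raise ValueError("coupling time constant must be positive")
    if len(stimulus) < 2:
        raise ValueError("stimulus must have at least 2 samples")
    dt = stimulus.sample_interval
    alpha = 1.0 - np.exp(-dt / coupling_tau)
    x = stimulus.potential
    y = np.empty_like(x)
    y[0] = x[0]
    for k in range(1, x.size):
        y[k] = y[k - 1] + alpha * (x[k] - y[k - 1])
    if noise_rms > 0:
        y = y + np.random.default_rng(seed).normal(0.0, noise_rms, size=y.size)
    return VoltageTrace(stimulus.time, y + offset)
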