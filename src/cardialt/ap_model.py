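"""Single-cell (space-clamped) four-variable minimal ventricular AP model.

The model describes the membrane potential ``u`` (dimensionless, rest at 0,
peak near 1.5) driven by three phenomenological currents -- fast inward
(sodium-like), slow outward (potassium-like) and slow inward (calcium-like) --
gated by three variables ``v``, ``w``, ``s`` with voltage-dependent, partly
Heaviside-switched kinetics.  The default constants reproduce canine
endocardial action-potential shape, restitution and conduction velocity.

At rest the state (u, v, w, s) = (0, 1, 1, s_rest) with
s_rest = (1 + tanh(k_s (0 - u_s)))/2 is an exact fixed point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .parameters import ModelParameters

__all__ = [
    "CellState", "APDSequence", "resting_state", "evaluate_currents",
    "evaluate_rate_functions", "step_cell", "run_cell_pacing",
    "rescale_voltage", "apd_sequence_from_trace",
    "DEFAULT_STIM_AMPLITUDE", "DEFAULT_STIM_DURATION_MS",
]

# Rectangular stimulus: 2 ms at 0.33/ms, about twice the diastolic threshold
# (the threshold for a 2 ms pulse from rest is near 0.167/ms at dt = 0.01 ms).
DEFAULT_STIM_DURATION_MS = 2.0
DEFAULT_STIM_AMPLITUDE = 0.33


@dataclass
class CellState:
    """Membrane potential and the three gates at a point."""

    u: float = 0.0
    v: float = 1.0
    w: float = 1.0
    s: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.u, self.v, self.w, self.s], dtype=np.float64)

    @classmethod
    def from_array(cls, a) -> "CellState":
        return cls(u=float(a[0]), v=float(a[1]), w=float(a[2]), s=float(a[3]))

    def validate(self) -> None:
        a = self.as_array()
        if not np.all(np.isfinite(a)):
            raise ValueError("non-finite cell state")


@dataclass
class APDSequence:
    """Per-beat action-potential durations from one paced trace.

    ``di_ms[k]`` is the diastolic interval between beat k and beat k+1
    (NaN for the last beat).  ``captured`` flags whether every delivered
    stimulus produced a detected beat (1:1 capture).
    """

    apds: np.ndarray
    cycle_length: float
    threshold_fraction: float = 0.2
    upstroke_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    di_ms: np.ndarray = field(default_factory=lambda: np.empty(0))
    n_stimuli: int = 0

    @property
    def n_beats(self) -> int:
        return len(self.apds)

    @property
    def captured(self) -> bool:
        return self.n_stimuli > 0 and self.n_beats == self.n_stimuli

    @property
    def delta_apd(self) -> np.ndarray:
        """Beat-to-beat differences APD[n+1] - APD[n]."""
        return np.diff(self.apds)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({
            "beat_index": np.arange(self.n_beats),
            "apd_ms": self.apds,
            "di_ms": self.di_ms,
            "cycle_length_ms": np.full(self.n_beats, self.cycle_length),
        })


def resting_state(params: ModelParameters | None = None) -> CellState:
    """The exact resting fixed point of the model."""
    p = params or ModelParameters()
    s_rest = (1.0 + math.tanh(p.k_s * (0.0 - p.u_s))) / 2.0
    return CellState(u=0.0, v=1.0, w=1.0, s=s_rest)


def rescale_voltage(u):
    """Convert dimensionless membrane potential to millivolts: 85.7 u - 84."""
    if np.ndim(u):
        return 85.7 * np.asarray(u, dtype=float) - 84.0
    return 85.7 * float(u) - 84.0


def evaluate_currents(state: CellState, params: ModelParameters | None = None):
    """The three current densities (J_fi, J_so, J_si), each in 1/ms."""
    p = params or ModelParameters()
    state.validate()
    return _kernels.currents(state.u, state.v, state.w, state.s, p.as_vector())


def evaluate_rate_functions(u: float, params: ModelParameters | None = None) -> dict:
    """Voltage-dependent time constants and gate asymptotes at voltage u."""
    p = params or ModelParameters()
    if not math.isfinite(u):
        raise ValueError("non-finite membrane potential")
    tau_vm, tau_wp, tau_wm, tau_so, tau_s, tau_o, v_inf, w_inf = \
        _kernels.rate_functions(float(u), p.as_vector())
    return {
        "tau_v_minus": tau_vm, "tau_w_plus": tau_wp, "tau_w_minus": tau_wm,
        "tau_so": tau_so, "tau_s": tau_s, "tau_o": tau_o,
        "v_inf": v_inf, "w_inf": w_inf,
    }


def step_cell(state: CellState, dt: float, i_stim: float = 0.0,
              params: ModelParameters | None = None) -> CellState:
    """One explicit-Euler update of the space-clamped model."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    p = params or ModelParameters()
    state.validate()
    du, dv, dw, ds = _kernels.derivatives(
        state.u, state.v, state.w, state.s, p.as_vector(), float(i_stim))
    return CellState(u=state.u + dt * du, v=state.v + dt * dv,
                     w=state.w + dt * dw, s=state.s + dt * ds)


def simulate_cell(params: ModelParameters, duration_ms: float, dt: float = 0.01,
                  cycle_length_ms: float = 0.0,
                  stim_amplitude: float = DEFAULT_STIM_AMPLITUDE,
                  stim_duration_ms: float = DEFAULT_STIM_DURATION_MS,
                  record_interval_ms: float = 0.1,
                  initial_state: CellState | None = None):
    """Integrate the 0D model; returns (time axis ms, u trace, final state).

    Stimuli are rectangular pulses delivered at t = 0, CL, 2 CL, ...
    (no stimulation when ``cycle_length_ms`` is 0).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    state = initial_state or resting_state(params)
    n_steps = int(round(duration_ms / dt))
    record_every = max(1, int(round(record_interval_ms / dt)))
    trace, final = _kernels.integrate_cell(
        params.as_vector(), state.as_array(), dt, n_steps,
        float(cycle_length_ms), float(stim_duration_ms), float(stim_amplitude),
        record_every)
    t = np.arange(len(trace)) * (record_every * dt)
    return t, trace, CellState.from_array(final)


def apd_sequence_from_trace(trace: np.ndarray, dt_ms: float,
                            threshold_fraction: float = 0.2,
                            cycle_length: float = float("nan"),
                            n_stimuli: int = 0) -> APDSequence:
    """APDs by threshold crossing at a fraction of the per-beat amplitude.

    The diastolic baseline is the trace minimum; beats are segmented by
    crossings of the threshold set from the global amplitude, then each APD
    is re-measured at ``threshold_fraction`` of that beat's own amplitude
    with sub-sample linear interpolation.
    """
    x = np.asarray(trace, dtype=float)
    baseline = float(np.min(x))
    amp = float(np.max(x)) - baseline
    if amp <= 0:
        return APDSequence(np.empty(0), cycle_length, threshold_fraction,
                           n_stimuli=n_stimuli)
    y = x - baseline
    thr = threshold_fraction * amp
    above = y >= thr
    rises = np.flatnonzero(~above[:-1] & above[1:]) + 1
    falls = np.flatnonzero(above[:-1] & ~above[1:]) + 1
    apds, ups, downs = [], [], []
    for r in rises:
        f = falls[falls > r]
        if len(f) == 0:
            break  # last beat not fully repolarized
        f = f[0]
        beat_amp = float(np.max(y[r:f])) if f > r else y[r]
        thr_b = threshold_fraction * beat_amp
        t_up = _cross_time(y, r, thr_b, dt_ms, backward=True)
        t_down = _cross_time(y, f, thr_b, dt_ms, backward=False)
        apds.append(t_down - t_up)
        ups.append(t_up)
        downs.append(t_down)
    apds = np.asarray(apds)
    ups = np.asarray(ups)
    downs = np.asarray(downs)
    di = np.full(len(apds), np.nan)
    if len(apds) > 1:
        di[:-1] = ups[1:] - downs[:-1]
    return APDSequence(apds=apds, cycle_length=cycle_length,
                       threshold_fraction=threshold_fraction,
                       upstroke_times=ups, di_ms=di, n_stimuli=n_stimuli)


def _cross_time(y, idx, thr, dt, backward):
    """Sub-sample time where y crosses thr adjacent to sample ``idx``."""
    n = len(y)
    if backward:
        i = idx
        while i > 0 and y[i - 1] >= thr:
            i -= 1
        if i == 0:
            return 0.0
        y0, y1 = y[i - 1], y[i]
    else:
        i = idx
        while i < n - 1 and y[i] >= thr:
            i += 1
        y0, y1 = y[i - 1], y[i]
    if y1 == y0:
        return i * dt
    frac = (thr - y0) / (y1 - y0)
    return (i - 1 + frac) * dt


def run_cell_pacing(params: ModelParameters | None = None,
                    cycle_length: float = 500.0, n_beats: int = 10,
                    threshold_fraction: float = 0.2, dt: float = 0.01,
                    stim_amplitude: float = DEFAULT_STIM_AMPLITUDE,
                    stim_duration_ms: float = DEFAULT_STIM_DURATION_MS,
                    initial_state: CellState | None = None) -> APDSequence:
    """Pace the 0D model at a fixed cycle length and measure per-beat APDs.

    Loss of 1:1 capture is reported through ``APDSequence.captured`` /
    ``n_stimuli`` rather than raised.
    """
    p = params or ModelParameters()
    if n_beats < 2:
        raise ValueError("need at least 2 beats")
    if cycle_length <= stim_duration_ms:
        raise ValueError("cycle length must exceed the stimulus duration")
    t, trace, _ = simulate_cell(
        p, duration_ms=cycle_length * n_beats, dt=dt,
        cycle_length_ms=cycle_length, stim_amplitude=stim_amplitude,
        stim_duration_ms=stim_duration_ms, initial_state=initial_state)
    dt_out = float(t[1] - t[0]) if len(t) > 1 else dt
    return apd_sequence_from_trace(trace, dt_out, threshold_fraction,
                                   cycle_length, n_beats)
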