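"""Leaky integrate-and-fire E/I network simulation.

Membrane dynamics (one equation per population, drive c in current units,
R*c in mV with R = 1 MΩ):

    tau_m dv/dt = -(v - V_L) - R*I_exc(v,t) - R*I_inh(v,t) + R*I_drive(t)

where each synaptic term is a sum over presynaptic spikes of a normalized
difference-of-exponentials kernel multiplied by the instantaneous driving
force (v - E_syn):

    I(v,t) = sum_j w_ij sum_k beta(t - t_jk) * (v - E_syn)
    beta(s) = 0                                           for s < d
            = (exp(-(s-d)/tau_d) - exp(-(s-d)/tau_r)) / (tau_d - tau_r)
                                                          for s >= d

Because every synapse of a given transmitter type shares (tau_d, tau_r),
the double sum collapses exactly into two per-neuron first-order filter
states per transmitter type, incremented by w at delayed presynaptic spike
arrivals and decayed exponentially in between.  The simulator integrates
the membrane with a fixed-step exponential-Euler scheme (the conductance
term is held constant over a step, so the per-step update is the exact
solution of a linear ODE), records a spike when v >= V_th at the end of a
step, and resets v to V_reset.  No refractory period is modelled.

An isolated-population fast path (all synapses absent) and a closed-form
constant-drive rate oracle are provided for validation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np

from .stimulus import StimulusEnsemble

__all__ = [
    "NeuronParams",
    "SynapseParams",
    "Connectivity",
    "SimulationGrid",
    "SpikeRecord",
    "StateTrace",
    "CountVector",
    "build_connectivity",
    "synaptic_kernel",
    "kernel_peak_time",
    "simulate",
    "simulate_isolated",
    "isolated_rate_closed_form",
    "spike_counts",
    "firing_rates",
]


@dataclass(frozen=True)
class NeuronParams:
    """LIF membrane parameters: times in ms, potentials in mV, R in MΩ."""

    tau_m: float
    resistance: float = 1.0
    v_leak: float = -65.0
    v_thresh: float = -63.0
    v_reset: float = -65.0

    def __post_init__(self) -> None:
        if self.tau_m <= 0:
            raise ValueError("tau_m must be > 0")
        if self.resistance <= 0:
            raise ValueError("resistance must be > 0")
        if self.v_thresh <= self.v_reset:
            raise ValueError("v_thresh must exceed v_reset")


@dataclass(frozen=True)
class SynapseParams:
    """One transmitter type: weight scale, kernel time constants, reversal
    potential and axonal delay (all times in ms)."""

    strength: float
    tau_decay: float
    tau_rise: float
    e_rev: float
    delay: float = 0.0

    def __post_init__(self) -> None:
        if self.strength < 0:
            raise ValueError("strength must be >= 0")
        if not (self.tau_decay > self.tau_rise > 0):
            raise ValueError("require tau_decay > tau_rise > 0")
        if self.delay < 0:
            raise ValueError("delay must be >= 0")

    def kernel_compatible(self, other: "SynapseParams") -> bool:
        return (
            self.tau_decay == other.tau_decay
            and self.tau_rise == other.tau_rise
            and self.e_rev == other.e_rev
            and self.delay == other.delay
        )


@dataclass(frozen=True)
class Connectivity:
    """Weight matrices; w_xy[i, j] is the weight from presynaptic neuron j of
    population y onto postsynaptic neuron i of population x."""

    w_ee: np.ndarray  # E <- E, (n_e, n_e)
    w_ei: np.ndarray  # I <- E, (n_i, n_e)
    w_ie: np.ndarray  # E <- I, (n_e, n_i)
    w_ii: np.ndarray  # I <- I, (n_i, n_i)
    connection_prob: float

    def __post_init__(self) -> None:
        for name in ("w_ee", "w_ei", "w_ie", "w_ii"):
            arr = np.asarray(getattr(self, name), dtype=float).copy()
            arr.flags.writeable = False
            object.__setattr__(self, name, arr)
        n_e, n_i = self.n_e, self.n_i
        if self.w_ee.shape != (n_e, n_e) or self.w_ii.shape != (n_i, n_i):
            raise ValueError("recurrent weight matrices must be square")
        if self.w_ei.shape != (n_i, n_e) or self.w_ie.shape != (n_e, n_i):
            raise ValueError("cross-population weight matrix shapes inconsistent")
        if np.any(np.diagonal(self.w_ee) != 0) or np.any(np.diagonal(self.w_ii) != 0):
            raise ValueError("self-connections are not allowed")

    @property
    def n_e(self) -> int:
        return self.w_ee.shape[0]

    @property
    def n_i(self) -> int:
        return self.w_ii.shape[0]

    def is_empty(self) -> bool:
        return not (
            self.w_ee.any() or self.w_ei.any() or self.w_ie.any() or self.w_ii.any()
        )


def build_connectivity(
    n_e: int,
    n_i: int,
    rho: float,
    g_ee: float,
    g_ei: float,
    g_ie: float,
    g_ii: float,
    seed: int | np.random.Generator,
) -> Connectivity:
    """Sample Bernoulli(rho) connectivity; an existing connection carries the
    full projection strength g.  Self-connections are excluded even at
    rho = 1 (neurons connect to *other* neurons)."""
    if not 0.0 <= rho <= 1.0:
        raise ValueError("rho must lie in [0, 1]")
    for name, g in (("g_ee", g_ee), ("g_ei", g_ei), ("g_ie", g_ie), ("g_ii", g_ii)):
        if g < 0:
            raise ValueError(f"{name} must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    def block(n_post: int, n_pre: int, g: float, recurrent: bool) -> np.ndarray:
        mask = rng.random((n_post, n_pre)) < rho
        w = np.where(mask, g, 0.0)
        if recurrent:
            np.fill_diagonal(w, 0.0)
        return w

    return Connectivity(
        w_ee=block(n_e, n_e, g_ee, True),
        w_ei=block(n_i, n_e, g_ei, False),
        w_ie=block(n_e, n_i, g_ie, False),
        w_ii=block(n_i, n_i, g_ii, True),
        connection_prob=float(rho),
    )


def synaptic_kernel(t_since_spike, params: SynapseParams):
    """Normalized double-exponential kernel beta evaluated at time(s) since
    the presynaptic spike (units 1/ms; integrates to 1 over [0, inf))."""
    t = np.asarray(t_since_spike, dtype=float)
    s = t - params.delay
    val = np.where(
        s >= 0.0,
        (np.exp(-np.clip(s, 0.0, None) / params.tau_decay)
         - np.exp(-np.clip(s, 0.0, None) / params.tau_rise))
        / (params.tau_decay - params.tau_rise),
        0.0,
    )
    return val if val.ndim else float(val)


def kernel_peak_time(params: SynapseParams) -> float:
    """Time of the kernel maximum: d + tau_d*tau_r/(tau_d-tau_r) * ln(tau_d/tau_r)."""
    td, tr = params.tau_decay, params.tau_rise
    return params.delay + td * tr / (td - tr) * math.log(td / tr)


@dataclass(frozen=True)
class SpikeRecord:
    """Spike times (ms) with neuron ids and population labels.

    Neurons 0..n_e-1 are excitatory, n_e..n_e+n_i-1 inhibitory.  Times are
    quantized to the integration step and strictly increasing per neuron.
    """

    neuron_ids: np.ndarray
    times: np.ndarray
    n_e: int
    n_i: int
    duration: float

    def __post_init__(self) -> None:
        ids = np.asarray(self.neuron_ids, dtype=np.intp).copy()
        times = np.asarray(self.times, dtype=float).copy()
        ids.flags.writeable = False
        times.flags.writeable = False
        object.__setattr__(self, "neuron_ids", ids)
        object.__setattr__(self, "times", times)
        if ids.shape != times.shape:
            raise ValueError("neuron_ids and times must have equal length")

    @property
    def n_neurons(self) -> int:
        return self.n_e + self.n_i

    def population(self, neuron: int) -> str:
        return "E" if neuron < self.n_e else "I"

    def spike_times(self, neuron: int) -> np.ndarray:
        return np.sort(self.times[self.neuron_ids == neuron])

    def population_times(self, population: Literal["E", "I", "all"] = "all") -> np.ndarray:
        if population == "all":
            return np.sort(self.times)
        if population == "E":
            return np.sort(self.times[self.neuron_ids < self.n_e])
        return np.sort(self.times[self.neuron_ids >= self.n_e])


@dataclass(frozen=True)
class CountVector:
    """Per-neuron spike counts within a window T (the 'output image')."""

    counts: np.ndarray
    window: float

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64).copy()
        counts.flags.writeable = False
        object.__setattr__(self, "counts", counts)
        if self.window <= 0:
            raise ValueError("window must be > 0")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def n_neurons(self) -> int:
        return int(self.counts.shape[0])


@dataclass(frozen=True)
class StateTrace:
    """Optional per-step state: membrane potentials and summed synaptic
    currents (current units; positive = as entering the RHS of the membrane
    equation before the leading minus sign).

    i_ee / i_ie: per-E-neuron summed currents from E and I sources.
    i_ei / i_ii: per-I-neuron summed currents from E and I sources.
    """

    time: np.ndarray
    v_e: Optional[np.ndarray] = None
    v_i: Optional[np.ndarray] = None
    i_ee: Optional[np.ndarray] = None
    i_ie: Optional[np.ndarray] = None
    i_ei: Optional[np.ndarray] = None
    i_ii: Optional[np.ndarray] = None


def _delay_steps(delay: float, dt: float) -> int:
    steps = max(1, int(round(delay / dt)))
    if abs(steps * dt - delay) > 1e-9 and delay >= dt:
        warnings.warn(
            f"synaptic delay {delay} ms is not a multiple of dt={dt} ms; "
            f"rounded to {steps * dt} ms",
            stacklevel=3,
        )
    return steps


def _noise_sd_effective(noise_sd: float, dt: float, scaling: str) -> float:
    if scaling == "none":
        return noise_sd
    if scaling == "sqrt_dt":
        return noise_sd / math.sqrt(dt)
    raise ValueError("noise_scaling must be 'none' or 'sqrt_dt'")


@dataclass(frozen=True)
class SimulationGrid:
    """Fixed integration grid; duration T and step dt in ms."""

    dt: float = 0.05
    duration: float = 300.0
    initial_condition_policy: Literal["at-reset", "uniform-random"] = "at-reset"

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        n = self.duration / self.dt
        if abs(n - round(n)) > 1e-6:
            raise ValueError("duration must be a whole number of steps")
        if self.initial_condition_policy not in ("at-reset", "uniform-random"):
            raise ValueError("unknown initial_condition_policy")

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.dt))


def _initial_v(
    params: NeuronParams,
    n: int,
    policy: str,
    rng: Optional[np.random.Generator],
) -> np.ndarray:
    if policy == "at-reset":
        return np.full(n, params.v_reset, dtype=float)
    if rng is None:
        raise ValueError("uniform-random initial conditions need an RNG")
    return rng.uniform(params.v_reset, params.v_thresh, size=n)


def simulate(
    e_params: NeuronParams,
    i_params: NeuronParams,
    syn_ee: SynapseParams,
    syn_ei: SynapseParams,
    syn_ie: SynapseParams,
    syn_ii: SynapseParams,
    conn: Connectivity,
    stim: StimulusEnsemble,
    bg: StimulusEnsemble,
    grid: SimulationGrid,
    seed: int | np.random.Generator | None = 0,
    record_state: bool = False,
    noise_scaling: str = "none",
) -> tuple[SpikeRecord, Optional[StateTrace]]:
    """Integrate the coupled E/I network and return spikes (and, optionally,
    per-step potentials and summed synaptic currents).

    The four synapse parameter sets must agree on kernel shape within each
    transmitter type (EE with EI, and IE with II): the model gives each
    transmitter type one kernel, and the filter implementation relies on it.
    Projection strengths live in the connectivity matrices.
    """
    if not syn_ee.kernel_compatible(syn_ei):
        raise ValueError("EE and EI synapses must share kernel parameters")
    if not syn_ie.kernel_compatible(syn_ii):
        raise ValueError("IE and II synapses must share kernel parameters")
    n_e, n_i = conn.n_e, conn.n_i
    if stim.n_neurons != n_e:
        raise ValueError("stimulus ensemble size must equal n_e")
    if bg.n_neurons != n_i:
        raise ValueError("background ensemble size must equal n_i")
    dt, n_steps = grid.dt, grid.n_steps
    if dt > min(syn_ee.tau_rise, syn_ie.tau_rise):
        warnings.warn("dt exceeds a synaptic rise time; kernel under-resolved")
    if dt > min(syn_ee.delay, syn_ie.delay):
        warnings.warn("dt exceeds a synaptic delay; arrivals rounded up to one step")

    init_rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    v_e = _initial_v(e_params, n_e, grid.initial_condition_policy, init_rng)
    v_i = _initial_v(i_params, n_i, grid.initial_condition_policy, init_rng)

    d_steps_e = _delay_steps(syn_ee.delay, dt)  # delay of excitatory synapses
    d_steps_i = _delay_steps(syn_ie.delay, dt)  # delay of inhibitory synapses

    # Double-exponential filter states, one (a, b) pair per postsynaptic
    # neuron per transmitter type.  G = (a - b) / (tau_d - tau_r) equals the
    # full double sum over presynaptic spikes exactly.
    a_e_on_e = np.zeros(n_e); b_e_on_e = np.zeros(n_e)
    a_i_on_e = np.zeros(n_e); b_i_on_e = np.zeros(n_e)
    a_e_on_i = np.zeros(n_i); b_e_on_i = np.zeros(n_i)
    a_i_on_i = np.zeros(n_i); b_i_on_i = np.zeros(n_i)

    dec_ed = math.exp(-dt / syn_ee.tau_decay)
    dec_er = math.exp(-dt / syn_ee.tau_rise)
    dec_id = math.exp(-dt / syn_ie.tau_decay)
    dec_ir = math.exp(-dt / syn_ie.tau_rise)
    inv_span_e = 1.0 / (syn_ee.tau_decay - syn_ee.tau_rise)
    inv_span_i = 1.0 / (syn_ie.tau_decay - syn_ie.tau_rise)

    sd_s = _noise_sd_effective(stim.noise_sd, dt, noise_scaling)
    sd_b = _noise_sd_effective(bg.noise_sd, dt, noise_scaling)
    rng_s = stim.noise_rng()
    rng_b = bg.noise_rng()
    c_e = stim.strengths
    c_i = bg.strengths

    r_e, r_i = e_params.resistance, i_params.resistance
    e_rev_exc, e_rev_inh = syn_ee.e_rev, syn_ie.e_rev

    # spike index lists per step (spike at step m means time m*dt, m >= 1)
    spikes_e_steps: list[np.ndarray] = [np.empty(0, dtype=np.intp)] * (n_steps + 1)
    spikes_i_steps: list[np.ndarray] = [np.empty(0, dtype=np.intp)] * (n_steps + 1)
    out_ids: list[np.ndarray] = []
    out_steps: list[np.ndarray] = []

    if record_state:
        time = np.arange(n_steps) * dt
        tr_v_e = np.empty((n_steps, n_e)); tr_v_i = np.empty((n_steps, n_i))
        tr_iee = np.empty((n_steps, n_e)); tr_iie = np.empty((n_steps, n_e))
        tr_iei = np.empty((n_steps, n_i)); tr_iii = np.empty((n_steps, n_i))

    use_dense_e = conn.connection_prob >= 0.5
    for n in range(n_steps):
        # bring filter states from t_{n-1} to t_n, then add arrivals due now
        a_e_on_e *= dec_ed; b_e_on_e *= dec_er
        a_e_on_i *= dec_ed; b_e_on_i *= dec_er
        a_i_on_e *= dec_id; b_i_on_e *= dec_ir
        a_i_on_i *= dec_id; b_i_on_i *= dec_ir

        m_e = n - d_steps_e
        if m_e >= 1:
            idx = spikes_e_steps[m_e]
            if idx.size:
                inc_e = conn.w_ee[:, idx].sum(axis=1)
                inc_i = conn.w_ei[:, idx].sum(axis=1)
                a_e_on_e += inc_e; b_e_on_e += inc_e
                a_e_on_i += inc_i; b_e_on_i += inc_i
        m_i = n - d_steps_i
        if m_i >= 1:
            idx = spikes_i_steps[m_i]
            if idx.size:
                inc_e = conn.w_ie[:, idx].sum(axis=1)
                inc_i = conn.w_ii[:, idx].sum(axis=1)
                a_i_on_e += inc_e; b_i_on_e += inc_e
                a_i_on_i += inc_i; b_i_on_i += inc_i

        g_exc_e = (a_e_on_e - b_e_on_e) * inv_span_e
        g_inh_e = (a_i_on_e - b_i_on_e) * inv_span_i
        g_exc_i = (a_e_on_i - b_e_on_i) * inv_span_e
        g_inh_i = (a_i_on_i - b_i_on_i) * inv_span_i

        drive_e = c_e if sd_s == 0 else c_e * (1.0 + sd_s * rng_s.standard_normal(n_e))
        drive_i = c_i if sd_b == 0 else c_i * (1.0 + sd_b * rng_b.standard_normal(n_i))

        if record_state:
            tr_v_e[n] = v_e; tr_v_i[n] = v_i
            tr_iee[n] = g_exc_e * (v_e - e_rev_exc)
            tr_iie[n] = g_inh_e * (v_e - e_rev_inh)
            tr_iei[n] = g_exc_i * (v_i - e_rev_exc)
            tr_iii[n] = g_inh_i * (v_i - e_rev_inh)

        # exponential-Euler membrane update: dv/dt = -A v + B with G frozen
        a_coef = (1.0 + r_e * (g_exc_e + g_inh_e)) / e_params.tau_m
        b_coef = (
            e_params.v_leak
            + r_e * (g_exc_e * e_rev_exc + g_inh_e * e_rev_inh)
            + r_e * drive_e
        ) / e_params.tau_m
        decay = np.exp(-a_coef * dt)
        v_e = v_e * decay + (b_coef / a_coef) * (1.0 - decay)

        a_coef = (1.0 + r_i * (g_exc_i + g_inh_i)) / i_params.tau_m
        b_coef = (
            i_params.v_leak
            + r_i * (g_exc_i * e_rev_exc + g_inh_i * e_rev_inh)
            + r_i * drive_i
        ) / i_params.tau_m
        decay = np.exp(-a_coef * dt)
        v_i = v_i * decay + (b_coef / a_coef) * (1.0 - decay)

        if not (np.all(np.isfinite(v_e)) and np.all(np.isfinite(v_i))):
            raise FloatingPointError(
                f"non-finite membrane potential at t={(n + 1) * dt:.3f} ms; "
                "reduce dt or check parameters"
            )

        fired_e = np.flatnonzero(v_e >= e_params.v_thresh)
        if fired_e.size:
            v_e[fired_e] = e_params.v_reset
            spikes_e_steps[n + 1] = fired_e
            out_ids.append(fired_e)
            out_steps.append(np.full(fired_e.size, n + 1))
        fired_i = np.flatnonzero(v_i >= i_params.v_thresh)
        if fired_i.size:
            v_i[fired_i] = i_params.v_reset
            spikes_i_steps[n + 1] = fired_i
            out_ids.append(fired_i + n_e)
            out_steps.append(np.full(fired_i.size, n + 1))

    if out_ids:
        ids = np.concatenate(out_ids)
        times = np.concatenate(out_steps) * dt
    else:
        ids = np.empty(0, dtype=np.intp)
        times = np.empty(0, dtype=float)
    rec = SpikeRecord(
        neuron_ids=ids, times=times, n_e=n_e, n_i=n_i, duration=grid.duration
    )
    trace = None
    if record_state:
        trace = StateTrace(
            time=time, v_e=tr_v_e, v_i=tr_v_i,
            i_ee=tr_iee, i_ie=tr_iie, i_ei=tr_iei, i_ii=tr_iii,
        )
    return rec, trace


def simulate_isolated(
    params: NeuronParams,
    stim: StimulusEnsemble,
    grid: SimulationGrid,
    seed: int | np.random.Generator | None = 0,
    noise_scaling: str = "none",
) -> SpikeRecord:
    """Simulate the stimulus-driven population with every synapse absent.

    This is the ablation arm of the paired experiments: identical membrane
    model, identical stimulus realization and noise stream, zero coupling.
    """
    n = stim.n_neurons
    dt, n_steps = grid.dt, grid.n_steps
    init_rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    v = _initial_v(params, n, grid.initial_condition_policy, init_rng)
    sd = _noise_sd_effective(stim.noise_sd, dt, noise_scaling)
    rng_s = stim.noise_rng()
    c = stim.strengths
    decay = math.exp(-dt / params.tau_m)
    one_minus = 1.0 - decay
    out_ids: list[np.ndarray] = []
    out_steps: list[np.ndarray] = []
    for step in range(n_steps):
        drive = c if sd == 0 else c * (1.0 + sd * rng_s.standard_normal(n))
        v_inf = params.v_leak + params.resistance * drive
        v = v * decay + v_inf * one_minus
        fired = np.flatnonzero(v >= params.v_thresh)
        if fired.size:
            v[fired] = params.v_reset
            out_ids.append(fired)
            out_steps.append(np.full(fired.size, step + 1))
    if out_ids:
        ids = np.concatenate(out_ids)
        times = np.concatenate(out_steps) * dt
    else:
        ids = np.empty(0, dtype=np.intp)
        times = np.empty(0, dtype=float)
    return SpikeRecord(
        neuron_ids=ids, times=times, n_e=n, n_i=0, duration=grid.duration
    )


def isolated_rate_closed_form(c: float, params: NeuronParams) -> float:
    """Steady firing rate (Hz) of a noise-free LIF neuron under constant
    drive c, spiking from reset: 1000 / (tau_m * ln((V_inf - V_reset) /
    (V_inf - V_th))) with V_inf = V_L + R*c; zero below rheobase."""
    v_inf = params.v_leak + params.resistance * c
    if v_inf <= params.v_thresh:
        return 0.0
    isi = params.tau_m * math.log(
        (v_inf - params.v_reset) / (v_inf - params.v_thresh)
    )
    return 1000.0 / isi


def spike_counts(
    rec: SpikeRecord, window: float, population: Literal["E", "I", "all"] = "E"
) -> CountVector:
    """Per-neuron spike counts in (0, window] — the output image."""
    if window > rec.duration + 1e-9:
        raise ValueError("window exceeds simulation duration")
    if population == "E":
        lo, hi = 0, rec.n_e
    elif population == "I":
        lo, hi = rec.n_e, rec.n_e + rec.n_i
    else:
        lo, hi = 0, rec.n_e + rec.n_i
    sel = (rec.neuron_ids >= lo) & (rec.neuron_ids < hi) & (rec.times <= window)
    counts = np.bincount(rec.neuron_ids[sel] - lo, minlength=hi - lo)
    return CountVector(counts=counts, window=window)


def firing_rates(
    rec: SpikeRecord, duration: Optional[float] = None,
    population: Literal["E", "I", "all"] = "E",
) -> np.ndarray:
    """Per-neuron firing rates in Hz over the given window (default: the
    full simulation duration)."""
    duration = rec.duration if duration is None else duration
    cv = spike_counts(rec, duration, population)
    return 1000.0 * cv.counts / duration
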