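"""End-to-end studies: paired network/isolated runs, parameter sweeps,
current-decomposition mechanism analysis, synchrony spectra and rate images.

The central design is *paired*: the coupled E/I network and the matched
population of isolated neurons are simulated on the identical stimulus
realization and identical noise stream, so the efficiency ratio
I_C = I_E(network) / I_E(isolated) isolates the effect of the coupling.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from typing import Literal, Optional, Sequence

import numpy as np
import scipy.signal

from . import infometrics, network, stimulus
from .infometrics import EfficiencyReport, PairedEfficiency
from .network import (
    Connectivity,
    CountVector,
    NeuronParams,
    SimulationGrid,
    SpikeRecord,
    StateTrace,
    SynapseParams,
)
from .stimulus import (
    STREAM_BACKGROUND,
    STREAM_CONNECTIVITY,
    STREAM_INIT_ISOLATED,
    STREAM_INIT_NETWORK,
    STREAM_STIMULUS,
    BackgroundConfig,
    DiscretizedInputs,
    StimulusConfig,
    child_seed,
)

__all__ = [
    "ExperimentConfig",
    "PairedRunResult",
    "SweepResult",
    "CurrentComparison",
    "SynchronySpectrum",
    "run_paired",
    "sweep",
    "SWEEPABLE_PARAMETERS",
    "decompose_currents",
    "rate_decile_currents",
    "synchrony_spectrum",
    "rate_image",
    "image_entropy",
]


@dataclass(frozen=True)
class ExperimentConfig:
    """Flat parameter set for one study; defaults are the fully connected
    baseline (450 E / 150 I, all-to-all, high-frequency synchronized).

    Units: times ms, potentials mV, resistances MΩ, drives in current units
    such that R*c is mV; synaptic strengths are dimensionless weights on the
    normalized kernel.
    """

    # stimulus to E neurons
    m_s: float = 4.0
    delta_s: float = 0.5
    sigma_n_s: float = 0.5
    # background to I neurons
    m_b: float = 2.4
    delta_b: float = 0.0
    sigma_n_b: float = 0.0
    # populations and connectivity
    n_e: int = 450
    n_i: int = 150
    rho: float = 1.0
    g_ee: float = 1.2 / 600
    g_ei: float = 1.2 / 600
    g_ie: float = 7.0 / 600
    g_ii: float = 7.0 / 600
    # membranes
    tau_m_e: float = 50.0
    tau_m_i: float = 10.0
    r_e: float = 1.0
    r_i: float = 1.0
    v_leak: float = -65.0
    v_thresh: float = -63.0
    v_reset: float = -65.0
    # synapses
    tau_d_e: float = 6.0
    tau_r_e: float = 0.1
    e_syn_e: float = 0.0
    tau_d_i: float = 6.0
    tau_r_i: float = 0.1
    e_syn_i: float = -85.0
    delay: float = 0.2
    # integration and analysis
    dt: float = 0.05
    duration: float = 300.0
    init_policy: str = "at-reset"
    noise_scaling: str = "none"
    bin_width: float = 0.01
    log_base: float = 2.0
    # bookkeeping
    seed: int = 0
    n_repeats: int = 20

    def replace(self, **changes) -> "ExperimentConfig":
        return replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    # ---- component builders -------------------------------------------------
    def stimulus_config(self, master_seed: Optional[int] = None) -> StimulusConfig:
        master = self.seed if master_seed is None else master_seed
        return StimulusConfig(
            mean_strength=self.m_s,
            strength_sd=self.delta_s,
            noise_sd=self.sigma_n_s,
            n_neurons=self.n_e,
            seed=child_seed(master, STREAM_STIMULUS),
        )

    def background_config(self, master_seed: Optional[int] = None) -> BackgroundConfig:
        master = self.seed if master_seed is None else master_seed
        return BackgroundConfig(
            mean_strength=self.m_b,
            strength_sd=self.delta_b,
            noise_sd=self.sigma_n_b,
            n_neurons=self.n_i,
            seed=child_seed(master, STREAM_BACKGROUND),
        )

    def e_neuron_params(self) -> NeuronParams:
        return NeuronParams(
            tau_m=self.tau_m_e, resistance=self.r_e, v_leak=self.v_leak,
            v_thresh=self.v_thresh, v_reset=self.v_reset,
        )

    def i_neuron_params(self) -> NeuronParams:
        return NeuronParams(
            tau_m=self.tau_m_i, resistance=self.r_i, v_leak=self.v_leak,
            v_thresh=self.v_thresh, v_reset=self.v_reset,
        )

    def synapse_params(self) -> tuple[SynapseParams, SynapseParams, SynapseParams, SynapseParams]:
        exc = dict(tau_decay=self.tau_d_e, tau_rise=self.tau_r_e,
                   e_rev=self.e_syn_e, delay=self.delay)
        inh = dict(tau_decay=self.tau_d_i, tau_rise=self.tau_r_i,
                   e_rev=self.e_syn_i, delay=self.delay)
        return (
            SynapseParams(strength=self.g_ee, **exc),
            SynapseParams(strength=self.g_ei, **exc),
            SynapseParams(strength=self.g_ie, **inh),
            SynapseParams(strength=self.g_ii, **inh),
        )

    def grid(self) -> SimulationGrid:
        return SimulationGrid(
            dt=self.dt, duration=self.duration,
            initial_condition_policy=self.init_policy,
        )

    def connectivity(self, master_seed: Optional[int] = None) -> Connectivity:
        master = self.seed if master_seed is None else master_seed
        return network.build_connectivity(
            self.n_e, self.n_i, self.rho,
            self.g_ee, self.g_ei, self.g_ie, self.g_ii,
            seed=child_seed(master, STREAM_CONNECTIVITY),
        )


@dataclass(frozen=True)
class PairedRunResult:
    """Everything one paired run produces."""

    config: ExperimentConfig
    seed: int
    stim: stimulus.StimulusEnsemble
    inputs: DiscretizedInputs
    network_record: SpikeRecord
    isolated_record: SpikeRecord
    network_counts: CountVector
    isolated_counts: CountVector
    efficiency: PairedEfficiency
    trace: Optional[StateTrace] = None


def run_paired(
    cfg: ExperimentConfig,
    seed: Optional[int] = None,
    record_state: bool = False,
) -> PairedRunResult:
    """Simulate the coupled network and the isolated population on identical
    stimuli and return records, counts and the paired efficiency report."""
    master = cfg.seed if seed is None else seed
    stim = stimulus.draw_strengths(cfg.stimulus_config(master))
    bg = stimulus.draw_background(cfg.background_config(master))
    conn = cfg.connectivity(master)
    grid = cfg.grid()
    syn_ee, syn_ei, syn_ie, syn_ii = cfg.synapse_params()

    rec_net, trace = network.simulate(
        cfg.e_neuron_params(), cfg.i_neuron_params(),
        syn_ee, syn_ei, syn_ie, syn_ii,
        conn, stim, bg, grid,
        seed=child_seed(master, STREAM_INIT_NETWORK),
        record_state=record_state,
        noise_scaling=cfg.noise_scaling,
    )
    rec_iso = network.simulate_isolated(
        cfg.e_neuron_params(), stim, grid,
        seed=child_seed(master, STREAM_INIT_ISOLATED),
        noise_scaling=cfg.noise_scaling,
    )

    k_net = network.spike_counts(rec_net, cfg.duration, population="E")
    k_iso = network.spike_counts(rec_iso, cfg.duration, population="E")
    d = stimulus.discretize(stim.strengths, cfg.bin_width)
    paired = PairedEfficiency(
        network=infometrics.info_efficiency(k_net, d, base=cfg.log_base),
        isolated=infometrics.info_efficiency(k_iso, d, base=cfg.log_base),
    )
    return PairedRunResult(
        config=cfg, seed=master, stim=stim, inputs=d,
        network_record=rec_net, isolated_record=rec_iso,
        network_counts=k_net, isolated_counts=k_iso,
        efficiency=paired, trace=trace,
    )


SWEEPABLE_PARAMETERS = {
    "g_ie_to_e": "g_ie",  # inhibition onto excitatory neurons (Fig-9a style)
    "g_e_to_i": "g_ei",   # excitatory drive onto inhibitory neurons (9b)
    "delta_s": "delta_s",  # stimulus contrast (9c)
}

# Repeat seeds are derived from the master seed well away from the
# per-run component streams.
_SWEEP_STREAM_OFFSET = 1000


@dataclass(frozen=True)
class SweepResult:
    """Mean and sd of I_C over matched repeats, per grid value."""

    parameter: str
    values: np.ndarray
    ratios: np.ndarray  # shape (n_values, n_repeats)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.size < 3:
            raise ValueError("a sweep needs at least 3 grid values")
        if not (np.all(np.diff(values) > 0) or np.all(np.diff(values) < 0)):
            raise ValueError("sweep grid must be strictly monotone")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "ratios", np.asarray(self.ratios, dtype=float))

    @property
    def mean(self) -> np.ndarray:
        return self.ratios.mean(axis=1)

    @property
    def sd(self) -> np.ndarray:
        return self.ratios.std(axis=1, ddof=1) if self.ratios.shape[1] > 1 else np.zeros(
            self.ratios.shape[0]
        )


def sweep(
    cfg: ExperimentConfig,
    parameter: str,
    values: Sequence[float],
    n_repeats: Optional[int] = None,
    seed: Optional[int] = None,
) -> SweepResult:
    """Paired runs across a parameter grid with matched seeds per repeat.

    Repeat r uses the same master seed at every grid value, so differences
    along the grid are not confounded by different stimulus draws.
    """
    if parameter not in SWEEPABLE_PARAMETERS:
        raise ValueError(
            f"unknown sweep parameter {parameter!r}; "
            f"choose from {sorted(SWEEPABLE_PARAMETERS)}"
        )
    field_name = SWEEPABLE_PARAMETERS[parameter]
    n_repeats = cfg.n_repeats if n_repeats is None else n_repeats
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    master = cfg.seed if seed is None else seed
    repeat_seeds = [
        child_seed(master, _SWEEP_STREAM_OFFSET + r) for r in range(n_repeats)
    ]
    values = np.asarray(values, dtype=float)
    ratios = np.empty((values.size, n_repeats))
    for iv, value in enumerate(values):
        cfg_v = cfg.replace(**{field_name: float(value)})
        for ir, rseed in enumerate(repeat_seeds):
            res = run_paired(cfg_v, seed=rseed)
            ratios[iv, ir] = infometrics.efficiency_ratio(res.efficiency)
    return SweepResult(parameter=parameter, values=values, ratios=ratios)


@dataclass(frozen=True)
class CurrentComparison:
    """Time-resolved summed synaptic currents of a high-rate and a low-rate
    excitatory neuron from the same simulation, plus time averages."""

    high_neuron: int
    low_neuron: int
    time: np.ndarray
    exc_high: np.ndarray
    exc_low: np.ndarray
    inh_high: np.ndarray
    inh_low: np.ndarray

    @property
    def mean_exc_high(self) -> float:
        return float(np.abs(self.exc_high).mean())

    @property
    def mean_exc_low(self) -> float:
        return float(np.abs(self.exc_low).mean())

    @property
    def mean_inh_high(self) -> float:
        return float(np.abs(self.inh_high).mean())

    @property
    def mean_inh_low(self) -> float:
        return float(np.abs(self.inh_low).mean())


def _require_trace(trace: Optional[StateTrace]) -> StateTrace:
    if trace is None or trace.i_ee is None or trace.i_ie is None:
        raise ValueError(
            "state trace with synaptic currents required; "
            "rerun the simulation with record_state=True"
        )
    return trace


def decompose_currents(
    trace: Optional[StateTrace],
    rec: SpikeRecord,
    high_neuron: Optional[int] = None,
    low_neuron: Optional[int] = None,
) -> CurrentComparison:
    """Split the synaptic drive of two E neurons into its excitatory-source
    and inhibitory-source parts; defaults to the top- and bottom-rate
    excitatory neurons of the record."""
    trace = _require_trace(trace)
    rates = network.firing_rates(rec, population="E")
    if high_neuron is None:
        high_neuron = int(np.argmax(rates))
    if low_neuron is None:
        low_neuron = int(np.argmin(rates))
    return CurrentComparison(
        high_neuron=high_neuron,
        low_neuron=low_neuron,
        time=trace.time,
        exc_high=trace.i_ee[:, high_neuron],
        exc_low=trace.i_ee[:, low_neuron],
        inh_high=trace.i_ie[:, high_neuron],
        inh_low=trace.i_ie[:, low_neuron],
    )


def rate_decile_currents(
    trace: Optional[StateTrace], rec: SpikeRecord
) -> dict[str, float]:
    """Mean |excitatory| and |inhibitory| synaptic current for the top and
    bottom rate-decile excitatory neurons (population-level version of the
    two-neuron comparison)."""
    trace = _require_trace(trace)
    rates = network.firing_rates(rec, population="E")
    n = rates.size
    n_dec = max(1, n // 10)
    order = np.argsort(rates, kind="stable")
    bottom, top = order[:n_dec], order[-n_dec:]
    mean_abs = lambda arr, idx: float(np.abs(arr[:, idx]).mean())
    return {
        "exc_top": mean_abs(trace.i_ee, top),
        "exc_bottom": mean_abs(trace.i_ee, bottom),
        "inh_top": mean_abs(trace.i_ie, top),
        "inh_bottom": mean_abs(trace.i_ie, bottom),
    }


@dataclass(frozen=True)
class SynchronySpectrum:
    """Periodogram of the mean-subtracted population spike-time histogram.

    ``power`` is the raw periodogram (full frequency resolution, so a
    periodic volley train keeps its spectral line on-grid);
    ``smoothed_power`` is a short boxcar average over neighbouring
    frequencies.  The smoothing matters for detection: raw periodogram
    ordinates of even a Poisson spike train are exponentially distributed
    and their maximum routinely exceeds several times the median, whereas
    the averaged spectrum stays near its flat level unless a genuine
    oscillation is present.
    """

    frequencies: np.ndarray  # Hz
    power: np.ndarray
    smoothed_power: np.ndarray
    dominant_frequency: float

    @property
    def peak_ratio(self) -> float:
        """Peak of the smoothed spectrum over its median (>~3 indicates a
        genuine oscillation rather than a flat, Poisson-like spectrum)."""
        med = float(np.median(self.smoothed_power))
        peak = float(self.smoothed_power.max())
        return peak / med if med > 0 else float("inf")


def synchrony_spectrum(
    rec: SpikeRecord,
    bin_ms: float = 1.0,
    population: Literal["E", "I", "all"] = "I",
    smooth_bins: Optional[int] = None,
) -> SynchronySpectrum:
    """Quantify population synchrony: histogram spike times (default 1 ms
    bins), remove the mean, and locate the dominant nonzero frequency of
    the periodogram."""
    times = rec.population_times(population)
    if times.size < 2:
        raise ValueError("synchrony spectrum undefined for fewer than 2 spikes")
    n_bins = max(2, int(round(rec.duration / bin_ms)))
    hist, _ = np.histogram(times, bins=n_bins, range=(0.0, rec.duration))
    x = hist - hist.mean()
    freqs, power = scipy.signal.periodogram(x, fs=1000.0 / bin_ms, detrend=False)
    freqs, power = freqs[1:], power[1:]  # drop DC
    if smooth_bins is None:
        # wider smoothing for longer records keeps the null's tail in check
        smooth_bins = max(3, round(n_bins / 100))
    kernel = np.ones(min(smooth_bins, power.size))
    smoothed = np.convolve(power, kernel, mode="same") / np.convolve(
        np.ones_like(power), kernel, mode="same"
    )
    dominant = float(freqs[int(np.argmax(power))])
    return SynchronySpectrum(
        frequencies=freqs, power=power, smoothed_power=smoothed,
        dominant_frequency=dominant,
    )


def rate_image(values, rows: int = 20, cols: int = 20) -> np.ndarray:
    """Arrange the first rows*cols values as a gray image: cell (i, j) shows
    neuron cols*(i-1)+j (1-based), linearly mapped to levels 0–255 over the
    observed min–max.  Constant input maps to a uniform (all-zero) image."""
    values = np.asarray(values, dtype=float)
    if values.size < rows * cols:
        raise ValueError(f"need at least {rows * cols} values, got {values.size}")
    block = values[: rows * cols].reshape(rows, cols)
    lo, hi = block.min(), block.max()
    if hi == lo:
        return np.zeros((rows, cols), dtype=np.uint8)
    return np.round((block - lo) / (hi - lo) * 255.0).astype(np.uint8)


def image_entropy(img: np.ndarray, base: float = 2.0) -> float:
    """Entropy of the gray-level histogram of an 8-bit image."""
    hist = np.bincount(np.asarray(img, dtype=np.uint8).ravel(), minlength=256)
    p = hist / hist.sum()
    p = p[p > 0]
    return float(-(p * (np.log(p) / np.log(base))).sum())
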