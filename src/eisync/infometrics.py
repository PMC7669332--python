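"""Ensemble-entropy information measures for spike-count codes.

The "ensemble" here is the population of neurons observed once, not a set of
repeated trials: probabilities are occupancy proportions across neurons.
With discretized inputs s_j (proportions p(s_j)) and spike counts k_i in a
window T:

    S_S     = -sum_j p(s_j) log p(s_j)                  input entropy
    S_full  = -sum_k p(k) log p(k)                      output (count) entropy
    S_noise = -sum_j p(s_j) sum_k p(k|s_j) log p(k|s_j) conditional entropy
    S_I     = S_full - S_noise                          mutual information
    F_S     = mean_i k_i                                mean spike cost
    I_E     = S_I / F_S                                 bits per spike

All estimators are plug-in (maximum likelihood) with 0*log(0) := 0; no bias
correction is applied.  Logarithms are base 2 by default (bits); pass
``base=math.e`` for nats.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .network import CountVector
from .stimulus import DiscretizedInputs

__all__ = [
    "EfficiencyReport",
    "PairedEfficiency",
    "input_entropy",
    "full_entropy",
    "noise_entropy",
    "mutual_information",
    "info_efficiency",
    "efficiency_ratio",
]


def _entropy(p: np.ndarray, base: float) -> float:
    p = np.asarray(p, dtype=float)
    p = p[p > 0]
    if p.size == 0:
        return 0.0
    return float(-(p * (np.log(p) / math.log(base))).sum())


@dataclass(frozen=True)
class EfficiencyReport:
    """The six headline statistics of one population/window.

    ``efficiency`` is None when the population fired no spikes (bits per
    spike is undefined, not zero).
    """

    input_entropy: float
    full_entropy: float
    noise_entropy: float
    mutual_information: float
    mean_spikes: float
    efficiency: Optional[float]

    def __post_init__(self) -> None:
        if not -1e-9 <= self.noise_entropy <= self.full_entropy + 1e-9:
            raise ValueError("require 0 <= S_noise <= S_full")
        if abs(self.mutual_information - (self.full_entropy - self.noise_entropy)) > 1e-12:
            raise ValueError("S_I must equal S_full - S_noise")
        if self.mean_spikes < 0:
            raise ValueError("mean_spikes must be >= 0")

    def to_dict(self) -> dict:
        return {
            "input_entropy": self.input_entropy,
            "full_entropy": self.full_entropy,
            "noise_entropy": self.noise_entropy,
            "mutual_information": self.mutual_information,
            "mean_spikes": self.mean_spikes,
            "efficiency": self.efficiency,
        }


@dataclass(frozen=True)
class PairedEfficiency:
    """Network and isolated-population reports on the same stimulus draw."""

    network: EfficiencyReport
    isolated: EfficiencyReport

    @property
    def ratio(self) -> Optional[float]:
        """Efficiency ratio I_C = I_E(network) / I_E(isolated)."""
        if (
            self.network.efficiency is None
            or self.isolated.efficiency is None
            or self.isolated.efficiency == 0
        ):
            return None
        return self.network.efficiency / self.isolated.efficiency

    def to_dict(self) -> dict:
        return {
            "network": self.network.to_dict(),
            "isolated": self.isolated.to_dict(),
            "ratio": self.ratio,
        }


def input_entropy(d: DiscretizedInputs, base: float = 2.0) -> float:
    """Entropy S_S of the discretized input levels (occupied levels only)."""
    return _entropy(d.proportions, base)


def full_entropy(k: CountVector, base: float = 2.0) -> float:
    """Entropy S_full of the across-neuron spike-count distribution."""
    if k.n_neurons == 0:
        raise ValueError("empty count vector")
    counts = np.bincount(k.counts)
    return _entropy(counts / k.n_neurons, base)


def noise_entropy(k: CountVector, d: DiscretizedInputs, base: float = 2.0) -> float:
    """Conditional entropy S_noise of counts given the input level.

    p(k|s_j) is the within-level proportion of neurons with count k; levels
    holding a single neuron contribute nothing.
    """
    if k.n_neurons != d.n_items:
        raise ValueError("counts and discretized inputs must describe the same neurons")
    total = 0.0
    for j in range(d.n_levels):
        members = k.counts[d.assignments == j]
        if members.size <= 1:
            continue
        cond = np.bincount(members) / members.size
        total += d.proportions[j] * _entropy(cond, base)
    return total


def mutual_information(k: CountVector, d: DiscretizedInputs, base: float = 2.0) -> float:
    """Plug-in mutual information S_I = S_full - S_noise."""
    return full_entropy(k, base) - noise_entropy(k, d, base)


def info_efficiency(
    k: CountVector, d: DiscretizedInputs, base: float = 2.0
) -> EfficiencyReport:
    """Full report: entropies, mutual information, spike cost, bits/spike."""
    s_s = input_entropy(d, base)
    s_full = full_entropy(k, base)
    s_noise = noise_entropy(k, d, base)
    s_i = s_full - s_noise
    f_s = float(k.counts.mean())
    eff = s_i / f_s if f_s > 0 else None
    return EfficiencyReport(
        input_entropy=s_s,
        full_entropy=s_full,
        noise_entropy=s_noise,
        mutual_information=s_i,
        mean_spikes=f_s,
        efficiency=eff,
    )


def efficiency_ratio(p: PairedEfficiency) -> float:
    """I_C, raising when the isolated efficiency is zero or undefined."""
    r = p.ratio
    if r is None:
        raise ZeroDivisionError(
            "efficiency ratio undefined: isolated efficiency is zero or undefined"
        )
    return r
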