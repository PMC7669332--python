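"""Synthetic stimulus / background drive generation and input discretization.

The only information-bearing input to the excitatory population is a vector of
per-neuron constant stimulus strengths ``c_i`` drawn once from a normal
distribution (mean ``m_s``, sd ``delta_s``).  During simulation each neuron's
instantaneous drive is the multiplicatively noise-corrupted value

    I_i(t) = c_i * (1 + eps_i(t)),    eps_i(t) ~ N(0, sigma_n) i.i.d.

Inhibitory neurons receive a background drive of identical structure
(``m_b``, ``delta_b``, ``sigma_n_b``).  For the entropy analysis the
continuous strengths are discretized onto a grid of levels ``s_j = j * dx``
(nearest-multiple assignment), mimicking the finite amplitude resolution of
a sensory channel.

Noise discretization policy: one independent normal deviate is drawn per
neuron per integration step and held constant over the step.  By default no
``1/sqrt(dt)`` scaling is applied, so the effective noise power depends on
the step size; reference configurations therefore pin ``dt``.  The
alternative white-noise-density convention is available via
``noise_scaling="sqrt_dt"`` on the simulators.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StimulusConfig",
    "BackgroundConfig",
    "StimulusEnsemble",
    "DiscretizedInputs",
    "draw_strengths",
    "draw_background",
    "noise_value",
    "discretize",
    "child_seed",
    "derived_rng",
]

# Named sub-streams spawned from a master seed.  Every consumer of
# randomness gets its own child stream so that, e.g., adding background
# noise to one arm of a paired experiment cannot perturb the stimulus
# noise of the other arm.
STREAM_STIMULUS = 0
STREAM_BACKGROUND = 1
STREAM_CONNECTIVITY = 2
STREAM_INIT_NETWORK = 3
STREAM_INIT_ISOLATED = 4

# Within an ensemble's own seed: sub-key 0 draws the frozen strengths,
# sub-key 1 feeds the per-step noise stream.
_KEY_STRENGTHS = 0
_KEY_NOISE = 1


def child_seed(master_seed: int, stream: int) -> int:
    """Derive a reproducible 31-bit child seed from a master seed."""
    ss = np.random.SeedSequence(master_seed, spawn_key=(stream,))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def derived_rng(seed: int, stream: int) -> np.random.Generator:
    """Generator for one named sub-stream of ``seed``."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


def _validate_drive_config(cfg) -> None:
    for name in ("mean_strength", "strength_sd", "noise_sd"):
        v = getattr(cfg, name)
        if not math.isfinite(v):
            raise ValueError(f"{name} must be finite, got {v!r}")
    if cfg.strength_sd < 0:
        raise ValueError("strength_sd must be >= 0")
    if cfg.noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if cfg.n_neurons < 1:
        raise ValueError("n_neurons must be >= 1")


@dataclass(frozen=True)
class StimulusConfig:
    """Distribution of the constant stimulus strengths to excitatory neurons.

    mean_strength and strength_sd are in drive (current) units; with a 1 MΩ
    membrane resistance, R*c is directly in mV.  noise_sd is the sd of the
    dimensionless multiplicative noise.
    """

    mean_strength: float
    strength_sd: float
    noise_sd: float
    n_neurons: int
    seed: int

    def __post_init__(self) -> None:
        _validate_drive_config(self)


@dataclass(frozen=True)
class BackgroundConfig:
    """Background drive to the inhibitory population; same structure as the
    stimulus (homogeneous when strength_sd = noise_sd = 0)."""

    mean_strength: float
    strength_sd: float
    noise_sd: float
    n_neurons: int
    seed: int

    def __post_init__(self) -> None:
        _validate_drive_config(self)


@dataclass(frozen=True)
class StimulusEnsemble:
    """A frozen draw of per-neuron constant strengths plus its noise process.

    The strengths array is immutable so that the exact same realization can
    be reused across the paired (network vs isolated) arms of an experiment.
    """

    strengths: np.ndarray
    noise_sd: float
    seed: int

    def __post_init__(self) -> None:
        arr = np.asarray(self.strengths, dtype=float).copy()
        arr.flags.writeable = False
        object.__setattr__(self, "strengths", arr)
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def n_neurons(self) -> int:
        return self.strengths.shape[0]

    def noise_rng(self) -> np.random.Generator:
        """Fresh generator positioned at the start of this ensemble's noise
        stream.  Two calls return identically-seeded generators, which is
        what makes paired arms see bitwise-identical noise."""
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(_KEY_NOISE,))
        )


def draw_strengths(cfg: StimulusConfig) -> StimulusEnsemble:
    """Draw the frozen per-neuron strengths c_i ~ N(mean, sd)."""
    rng = np.random.default_rng(
        np.random.SeedSequence(cfg.seed, spawn_key=(_KEY_STRENGTHS,))
    )
    strengths = cfg.mean_strength + cfg.strength_sd * rng.standard_normal(cfg.n_neurons)
    return StimulusEnsemble(strengths=strengths, noise_sd=cfg.noise_sd, seed=cfg.seed)


def draw_background(cfg: BackgroundConfig) -> StimulusEnsemble:
    """Background drive to inhibitory neurons; identical contract to
    :func:`draw_strengths`."""
    return draw_strengths(
        StimulusConfig(
            mean_strength=cfg.mean_strength,
            strength_sd=cfg.strength_sd,
            noise_sd=cfg.noise_sd,
            n_neurons=cfg.n_neurons,
            seed=cfg.seed,
        )
    )


def noise_value(
    ensemble: StimulusEnsemble, neuron: int, rng: np.random.Generator
) -> float:
    """One instantaneous drive sample c_i*(1 + eps), eps ~ N(0, noise_sd)."""
    if not 0 <= neuron < ensemble.n_neurons:
        raise IndexError(f"neuron index {neuron} out of range")
    eps = rng.normal(0.0, ensemble.noise_sd) if ensemble.noise_sd > 0 else 0.0
    return float(ensemble.strengths[neuron] * (1.0 + eps))


@dataclass(frozen=True)
class DiscretizedInputs:
    """Inputs binned to levels s_j = j*dx with occupancy proportions p(s_j).

    Only occupied levels are kept.  ``assignments[i]`` indexes the level of
    neuron i within ``levels``; ``proportions`` sum to one.
    """

    bin_width: float
    levels: np.ndarray
    assignments: np.ndarray
    proportions: np.ndarray

    def __post_init__(self) -> None:
        levels = np.asarray(self.levels, dtype=float)
        assignments = np.asarray(self.assignments, dtype=np.intp)
        proportions = np.asarray(self.proportions, dtype=float)
        for name, arr in (("levels", levels), ("assignments", assignments),
                          ("proportions", proportions)):
            arr = arr.copy()
            arr.flags.writeable = False
            object.__setattr__(self, name, arr)
        if self.bin_width <= 0:
            raise ValueError("bin_width must be > 0")
        if abs(self.proportions.sum() - 1.0) > 1e-12:
            raise ValueError("proportions must sum to 1")
        if self.assignments.min(initial=0) < 0 or (
            self.assignments.max(initial=-1) >= self.levels.shape[0]
        ):
            raise ValueError("assignments reference nonexistent levels")

    @property
    def n_levels(self) -> int:
        return int(self.levels.shape[0])

    @property
    def n_items(self) -> int:
        return int(self.assignments.shape[0])


def discretize(strengths, bin_width: float) -> DiscretizedInputs:
    """Assign each strength to its nearest multiple of ``bin_width``.

    Level values are s_j = j*dx; proportions are occupancy counts over the
    number of inputs.  Unoccupied levels are omitted.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    strengths = np.asarray(strengths, dtype=float)
    if strengths.ndim != 1 or strengths.size == 0:
        raise ValueError("strengths must be a nonempty 1-D sequence")
    idx = np.rint(strengths / bin_width).astype(np.int64)
    unique_idx, assignments, counts = np.unique(
        idx, return_inverse=True, return_counts=True
    )
    return DiscretizedInputs(
        bin_width=float(bin_width),
        levels=unique_idx * bin_width,
        assignments=assignments,
        proportions=counts / strengths.size,
    )
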