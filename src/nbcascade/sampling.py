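"""Random parameter assignment for the continuous model.

Regulation strengths and default promoter activities are redrawn
independently for every trial.  Strength entries corresponding to absent
Boolean regulations are exactly zero; present regulations are drawn with
the sign of the Boolean network.  Magnitudes are log-uniform (regulation
strengths span two decades, basal promoter activities of the regulated
genes span two decades below the strong-promoter scale); the promoter
activities of the input genes hb and x, which only set the amplitude of
the imposed pulses, are drawn linearly around 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import SignNetwork

_SCALES = ("linear", "log")


@dataclass(frozen=True)
class Interval:
    lo: float
    hi: float
    scale: str = "log"

    def __post_init__(self):
        if not (0 < self.lo < self.hi):
            raise ValueError(f"need 0 < lo < hi, got ({self.lo}, {self.hi})")
        if self.scale not in _SCALES:
            raise ValueError(f"scale must be one of {_SCALES}")

    def sample(self, rng: np.random.Generator, size=None):
        if self.scale == "log":
            return np.exp(rng.uniform(np.log(self.lo), np.log(self.hi),
                                      size=size))
        return rng.uniform(self.lo, self.hi, size=size)


@dataclass(frozen=True)
class ParameterRanges:
    activation: Interval = field(default_factory=lambda: Interval(0.05, 5.0))
    repression: Interval = field(default_factory=lambda: Interval(0.05, 5.0))
    s_regulated: Interval = field(default_factory=lambda: Interval(0.01, 1.0))
    s_input: Interval = field(
        default_factory=lambda: Interval(0.5, 2.0, "linear"))


def rng_from(seed: int, *stream) -> np.random.Generator:
    """Deterministic generator for (seed, stream identifiers)."""
    return np.random.default_rng([int(seed), *map(_hash_part, stream)])


def _hash_part(x) -> int:
    if isinstance(x, int):
        return x & 0xFFFFFFFF
    return abs(hash(str(x))) & 0xFFFFFFFF


def sample_strengths(network: SignNetwork, ranges: ParameterRanges,
                     rng: np.random.Generator, n: int = 1) -> np.ndarray:
    """(n, 3, 5) regulation-strength matrices matching the Boolean signs."""
    J = network.J
    out = np.zeros((n, 3, 5))
    act = J == 1
    rep = J == -5
    n_act = int(act.sum())
    n_rep = int(rep.sum())
    if n_act:
        out[:, act] = ranges.activation.sample(rng, (n, n_act))
    if n_rep:
        out[:, rep] = -ranges.repression.sample(rng, (n, n_rep))
    return out


def sample_promoters(ranges: ParameterRanges, rng: np.random.Generator,
                     n: int = 1) -> np.ndarray:
    """(n, 5) default promoter activities in gene order hb,Kr,pdm,cas,x."""
    out = np.empty((n, 5))
    out[:, 0] = ranges.s_input.sample(rng, n)
    out[:, 4] = ranges.s_input.sample(rng, n)
    out[:, 1:4] = ranges.s_regulated.sample(rng, (n, 3))
    return out


def sample_parameter_batch(network: SignNetwork, ranges: ParameterRanges,
                           rng: np.random.Generator, n: int):
    """Independent draws for n trials: (strengths (n,3,5), promoters (n,5))."""
    return (sample_strengths(network, ranges, rng, n),
            sample_promoters(ranges, rng, n))
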