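"""Architecture statistics of network ensembles.

The distance between two networks is the number of the twelve non-x
regulation slots whose sign class differs, after mapping positive
self-feedback (a +1 diagonal slot) to absence: regulations from x and
positive self-feedbacks are left out of the count because their existence
is not experimentally established.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import SignNetwork, TARGETS
from .scan import _as_matrix

#: diagonal (self-regulation) positions within the 3x4 non-x block
_SELF = [(0, 1), (1, 2), (2, 3)]


def _canon12(Js: np.ndarray, neglect_positive_self: bool = True) -> np.ndarray:
    """Non-x block with +1 self-slots mapped to 0 (the counting convention)."""
    J12 = np.array(Js[..., :, :4], dtype=np.int8, copy=True)
    if neglect_positive_self:
        for i, j in _SELF:
            d = J12[..., i, j]
            d[d == 1] = 0
    return J12


def distance(a, b, neglect_positive_self: bool = True) -> int:
    """Number of differing regulations between two networks."""
    A = _canon12(_as_matrix([a]), neglect_positive_self)[0]
    B = _canon12(_as_matrix([b]), neglect_positive_self)[0]
    return int((A != B).sum())


@dataclass
class DistanceReport:
    n: int
    mean: float
    sd: float
    histogram: pd.DataFrame     # columns: distance, count

    def to_dict(self) -> dict:
        return {"n": self.n, "mean": self.mean, "sd": self.sd,
                "histogram": {int(r.distance): int(r["count"])
                              for _, r in self.histogram.iterrows()}}


def distances_to(items, reference: SignNetwork) -> np.ndarray:
    Js = _canon12(_as_matrix(items))
    ref = _canon12(reference.J[None])[0]
    return (Js != ref[None]).sum(axis=(1, 2))


def ensemble_distances(items, reference: SignNetwork) -> DistanceReport:
    d = distances_to(items, reference)
    vals, counts = np.unique(d, return_counts=True)
    hist = pd.DataFrame({"distance": vals, "count": counts})
    return DistanceReport(n=len(d), mean=float(d.mean()),
                          sd=float(d.std()), histogram=hist)


def all_possible_expectation(reference: SignNetwork) -> tuple[float, float]:
    """Exact mean and sd of the distance between the reference and a
    uniformly random network, computed slotwise.

    Under the counting convention each of the 9 off-diagonal slots
    mismatches with probability 2/3; a diagonal slot collapses +1 to 0 and
    mismatches a zero reference slot with probability 1/3.
    """
    ref = _canon12(reference.J[None])[0]
    mean = 0.0
    var = 0.0
    for i in range(3):
        for j in range(4):
            if (i, j) in _SELF:
                # candidate collapses to {0 (p=2/3), -5 (p=1/3)}
                p = 2 / 3 if ref[i, j] == -5 else 1 / 3
            else:
                p = 2 / 3
            mean += p
            var += p * (1 - p)
    return mean, float(np.sqrt(var))


def reconnect(network, rng: np.random.Generator,
              n_iterations: int = 1000) -> SignNetwork:
    """Random reconnection of the twelve non-x matrix elements.

    ``n_iterations`` pairwise swaps of slot values; the numbers of positive
    and negative regulations are preserved exactly.  x regulations are held
    fixed.
    """
    Js = _as_matrix([network])[0]
    flat = Js[:, :4].copy().reshape(12)
    for _ in range(n_iterations):
        i, j = rng.integers(0, 12, size=2)
        flat[i], flat[j] = flat[j], flat[i]
    out = Js.copy()
    out[:, :4] = flat.reshape(3, 4)
    return SignNetwork(out, include_x=True)


def reconnected_ensemble(items, rng: np.random.Generator,
                         per_network: int = 100,
                         n_iterations: int = 1000) -> list[SignNetwork]:
    out = []
    for it in items:
        for _ in range(per_network):
            out.append(reconnect(it, rng, n_iterations))
    return out


def collapse_self_feedback(items) -> list[SignNetwork]:
    """Map +1 self-slots to 0 and deduplicate; order-preserving."""
    Js = _as_matrix(items)
    collapsed = Js.copy()
    for i, j in _SELF:
        d = collapsed[:, i, j]
        d[d == 1] = 0
    seen = {}
    for J in collapsed:
        key = J.tobytes()
        if key not in seen:
            seen[key] = SignNetwork(J, include_x=bool(J[:, 4].any()) or True)
    return list(seen.values())
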