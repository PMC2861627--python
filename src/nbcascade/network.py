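"""Sign networks over the neuroblast temporal-patterning genes.

The model genes are hb (Hunchback), Kr (Krüppel), pdm (Pdm1/Pdm2), cas
(Castor), the input pulse svp (Seven-up) and the hypothetical early factor
x.  Only Kr, pdm and cas have computed dynamics; hb, svp and x enter as
imposed input trajectories.  A regulation carries one of three discrete
values: +1 (activation), 0 (absence) or -5 (strong repression, which
dominates any achievable sum of activators).

A candidate network is a 3x5 integer matrix ``J[target][regulator]`` with
targets (Kr, pdm, cas) and regulators (hb, Kr, pdm, cas, x).  The twelve
non-x slots (or all fifteen slots) map onto a canonical base-3 integer code
used by the exhaustive screens: slot ``s = 4 * target + regulator`` for the
non-x slots, x slots appended as ``12 + target``; digit 0 -> J = 0,
digit 1 -> J = +1, digit 2 -> J = -5, least-significant digit first.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

GENES = ("hb", "Kr", "pdm", "cas", "svp", "x")
TARGETS = ("Kr", "pdm", "cas")
REGULATORS = ("hb", "Kr", "pdm", "cas", "x")

#: admissible regulation values, in digit order of the base-3 encoding
VALUES = (0, 1, -5)
ACTIVATION = 1
REPRESSION = -5

N_NETWORKS_12 = 3 ** 12   # 531_441
N_NETWORKS_15 = 3 ** 15   # 14_348_907

_DIGIT_TO_VALUE = np.array(VALUES, dtype=np.int8)
_VALUE_TO_DIGIT = {0: 0, 1: 1, -5: 2}


class SignNetwork:
    """Immutable wrapper around the 3x5 regulation matrix.

    Parameters
    ----------
    matrix : array-like, shape (3, 5)
        Rows index targets (Kr, pdm, cas), columns regulators
        (hb, Kr, pdm, cas, x).  Entries must be in {0, +1, -5}.
    include_x : bool
        Whether the network lives in the 15-slot space.  A 12-slot network
        must have an all-zero x column.
    """

    __slots__ = ("J", "include_x")

    def __init__(self, matrix, include_x: bool = True):
        J = np.asarray(matrix, dtype=np.int8)
        if J.shape != (3, 5):
            raise ValueError(f"expected shape (3, 5), got {J.shape}")
        bad = set(np.unique(J)) - set(VALUES)
        if bad:
            raise ValueError(f"invalid regulation values {sorted(bad)}")
        if not include_x and J[:, 4].any():
            raise ValueError("12-slot network must have an empty x column")
        J.setflags(write=False)
        self.J = J
        self.include_x = bool(include_x)

    # -- encoding ---------------------------------------------------------
    @property
    def code(self) -> int:
        """Canonical base-3 integer code of the network."""
        c = 0
        slots = 15 if self.include_x else 12
        for s in reversed(range(slots)):
            tgt, reg = (s - 12, 4) if s >= 12 else divmod(s, 4)
            c = c * 3 + _VALUE_TO_DIGIT[int(self.J[tgt, reg])]
        return c

    @classmethod
    def from_code(cls, code: int, include_x: bool = True) -> "SignNetwork":
        slots = 15 if include_x else 12
        if not 0 <= code < 3 ** slots:
            raise ValueError(f"code {code} out of range for {slots} slots")
        J = np.zeros((3, 5), dtype=np.int8)
        c = code
        for s in range(slots):
            tgt, reg = (s - 12, 4) if s >= 12 else divmod(s, 4)
            J[tgt, reg] = _DIGIT_TO_VALUE[c % 3]
            c //= 3
        return cls(J, include_x=include_x)

    # -- conversions ------------------------------------------------------
    def with_x(self) -> "SignNetwork":
        return self if self.include_x else SignNetwork(self.J, include_x=True)

    def without_x(self) -> "SignNetwork":
        if self.J[:, 4].any():
            raise ValueError("network has x regulations; cannot drop x")
        return SignNetwork(self.J, include_x=False)

    def replace(self, regulator: str, target: str, value: int) -> "SignNetwork":
        J = self.J.copy()
        J[TARGETS.index(target), REGULATORS.index(regulator)] = value
        return SignNetwork(J, include_x=self.include_x)

    def __getitem__(self, key) -> int:
        target, regulator = key
        return int(self.J[TARGETS.index(target), REGULATORS.index(regulator)])

    def __eq__(self, other) -> bool:
        return (isinstance(other, SignNetwork)
                and np.array_equal(self.J, other.J)
                and self.include_x == other.include_x)

    def __hash__(self) -> int:
        return hash((self.J.tobytes(), self.include_x))

    def __repr__(self) -> str:
        edges = [f"{r}->{t}:{self[t, r]:+d}" for t in TARGETS
                 for r in REGULATORS if self[t, r]]
        return f"SignNetwork({', '.join(edges) or 'empty'})"

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {t: {r: int(self.J[i, j]) for j, r in enumerate(REGULATORS)}
                for i, t in enumerate(TARGETS)}

    @classmethod
    def from_dict(cls, d: dict, include_x: bool = True) -> "SignNetwork":
        J = np.zeros((3, 5), dtype=np.int8)
        for i, t in enumerate(TARGETS):
            for j, r in enumerate(REGULATORS):
                J[i, j] = d.get(t, {}).get(r, 0)
        return cls(J, include_x=include_x)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_json(cls, s: str, include_x: bool = True) -> "SignNetwork":
        return cls.from_dict(json.loads(s), include_x=include_x)

    def edge_list(self):
        """Edge-list rows (regulator, target, sign), nonzero slots only.

        svp -| hb is implicit in the dynamics and not part of the
        enumerated matrix, so it is not listed.
        """
        return [(r, t, int(self.J[i, j])) for i, t in enumerate(TARGETS)
                for j, r in enumerate(REGULATORS) if self.J[i, j]]

    @classmethod
    def from_edge_list(cls, rows, include_x: bool = True) -> "SignNetwork":
        J = np.zeros((3, 5), dtype=np.int8)
        for r, t, v in rows:
            J[TARGETS.index(t), REGULATORS.index(r)] = v
        return cls(J, include_x=include_x)


def drosophila_network(include_hb_to_cas: bool = True,
                       include_x: bool = False) -> SignNetwork:
    """The reconstructed *Drosophila* reference network.

    Activations hb->Kr, Kr->pdm, pdm->cas; repressions hb-|pdm, Kr-|cas,
    pdm-|Kr, cas-|pdm; the literature-suggested hb-|cas is included by
    default.  With ``include_x`` the two regulations from the predicted
    early factor (x->Kr activation, x-|cas repression) are added.
    """
    J = np.zeros((3, 5), dtype=np.int8)
    J[0, 0] = ACTIVATION    # hb -> Kr
    J[1, 1] = ACTIVATION    # Kr -> pdm
    J[2, 2] = ACTIVATION    # pdm -> cas
    J[1, 0] = REPRESSION    # hb -| pdm
    J[2, 1] = REPRESSION    # Kr -| cas
    J[0, 2] = REPRESSION    # pdm -| Kr
    J[1, 3] = REPRESSION    # cas -| pdm
    if include_hb_to_cas:
        J[2, 0] = REPRESSION    # hb -| cas
    if include_x:
        J[0, 4] = ACTIVATION    # x -> Kr
        J[2, 4] = REPRESSION    # x -| cas
    return SignNetwork(J, include_x=include_x)


def minimum_network() -> SignNetwork:
    """Regulations shared by every functional network (the minimum circuit).

    Equal to the *Drosophila* network with x, minus Kr->pdm, pdm->cas and
    hb-|cas.
    """
    net = drosophila_network(include_hb_to_cas=False, include_x=True)
    net = net.replace("Kr", "pdm", 0)
    net = net.replace("pdm", "cas", 0)
    return net


# -- genotypes ------------------------------------------------------------

@dataclass(frozen=True)
class GenotypeSpec:
    """A wild-type, loss-of-function or overexpression genotype.

    ``gene is None`` denotes wild type.  Clamps apply at every time step
    including t = 0: the clamped gene is held at 0 (loss) or 1
    (overexpression).
    """
    gene: str | None = None
    mode: str | None = None     # "loss" | "oe" | None

    def __post_init__(self):
        if self.gene is None:
            if self.mode is not None:
                raise ValueError("wild type takes no mode")
        else:
            if self.gene not in ("hb", "Kr", "pdm", "cas"):
                raise ValueError(f"no mutant genotypes for gene {self.gene!r}")
            if self.mode not in ("loss", "oe"):
                raise ValueError(f"mode must be 'loss' or 'oe', got {self.mode!r}")

    @property
    def is_wt(self) -> bool:
        return self.gene is None

    @property
    def clamp_value(self) -> int | None:
        if self.is_wt:
            return None
        return 0 if self.mode == "loss" else 1

    @property
    def name(self) -> str:
        if self.is_wt:
            return "wt"
        return self.gene + ("-" if self.mode == "loss" else "++")

    @classmethod
    def from_name(cls, name: str) -> "GenotypeSpec":
        if name == "wt":
            return cls()
        if name.endswith("++"):
            return cls(name[:-2], "oe")
        if name.endswith("-"):
            return cls(name[:-1], "loss")
        raise KeyError(f"unknown genotype {name!r}")


#: the nine genotypes with experimentally reported expression profiles
GENOTYPES: tuple[GenotypeSpec, ...] = (
    GenotypeSpec(),
    GenotypeSpec("hb", "loss"), GenotypeSpec("Kr", "loss"),
    GenotypeSpec("pdm", "loss"), GenotypeSpec("cas", "loss"),
    GenotypeSpec("hb", "oe"), GenotypeSpec("Kr", "oe"),
    GenotypeSpec("pdm", "oe"), GenotypeSpec("cas", "oe"),
)


def default_states() -> Iterator[tuple[int, int, int]]:
    """All 2^3 default-expression-state combinations (Kr, pdm, cas)."""
    for s in range(8):
        yield (s & 1, (s >> 1) & 1, (s >> 2) & 1)


@dataclass(frozen=True)
class InputSchedule:
    """Imposed input trajectories for a Boolean simulation.

    svp pulses at ``svp_step`` (fixed to 1), switching hb off from the next
    step; hb is ON for t < hb_off (clamps override).  x switches exactly
    once at ``t_x``: ON -> OFF polarity means x is ON for t < t_x.  The
    same schedule (in particular the same t_x) is used for all genotypes of
    one candidate network.
    """
    t_end: int = 10
    t_x: int = 1
    x_polarity: str = "on_off"     # "on_off" | "off_on"
    hb_off: int = 2
    svp_step: int = 1

    def __post_init__(self):
        if not 1 <= self.t_x <= self.t_end:
            raise ValueError("t_x must lie in [1, t_end]")
        if self.x_polarity not in ("on_off", "off_on"):
            raise ValueError(f"bad polarity {self.x_polarity!r}")

    def hb_input(self, t: int) -> int:
        return 1 if t < self.hb_off else 0

    def svp_input(self, t: int) -> int:
        return 1 if t == self.svp_step else 0

    def x_input(self, t: int) -> int:
        early = 1 if t < self.t_x else 0
        return early if self.x_polarity == "on_off" else 1 - early
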