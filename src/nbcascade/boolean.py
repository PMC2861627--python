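"""Synchronous Boolean dynamics of the temporal cascade.

The regulated genes Kr, pdm and cas update by thresholding their summed
regulatory input: next state 1 if the sum is positive, 0 if negative, and
the gene's default expression state if exactly zero.  hb, svp and x are
inputs: hb starts ON and is switched off permanently by the svp pulse at
t = 1; x switches once at t_x.  Clamped genes (mutant genotypes) hold
their clamp value at every step.

This module is the scalar reference implementation; the vectorized screen
in :mod:`nbcascade.scan` is validated against it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import GENES, GenotypeSpec, InputSchedule, SignNetwork

_GIDX = {g: i for i, g in enumerate(GENES)}
_REGULATED = ("Kr", "pdm", "cas")


@dataclass(frozen=True)
class BooleanState:
    hb: int
    Kr: int
    pdm: int
    cas: int
    svp: int = 0
    x: int = 0

    def as_tuple(self):
        return (self.hb, self.Kr, self.pdm, self.cas, self.svp, self.x)


class BooleanTrajectory:
    """Per-gene ON/OFF states over t = 0 .. t_end (length t_end + 1)."""

    def __init__(self, states: np.ndarray):
        states = np.asarray(states, dtype=np.int8)
        if states.ndim != 2 or states.shape[1] != len(GENES):
            raise ValueError("states must have one column per gene")
        self.states = states

    def __len__(self):
        return len(self.states)

    def gene(self, name: str) -> np.ndarray:
        return self.states[:, _GIDX[name]]

    def window(self, name: str) -> tuple[int, int, int]:
        """(first ON step, last ON step, number of ON steps); (-1,-1,0) if
        the gene is never expressed.  The window is the span between first
        and last expression; interior OFF gaps are not tracked here."""
        on = np.flatnonzero(self.gene(name))
        if on.size == 0:
            return (-1, -1, 0)
        return (int(on[0]), int(on[-1]), int(on.size))

    def to_frame(self) -> pd.DataFrame:
        """Tidy (t, gene, state) table."""
        t = np.repeat(np.arange(len(self)), len(GENES))
        gene = np.tile(np.array(GENES), len(self))
        return pd.DataFrame({"t": t, "gene": gene,
                             "state": self.states.ravel()})

    def strip_plot(self) -> str:
        lines = []
        for g in GENES:
            row = "".join("#" if v else "." for v in self.gene(g))
            lines.append(f"{g:>4s} {row}")
        return "\n".join(lines)


def step(state: BooleanState, t: int, network: SignNetwork,
         defaults: tuple[int, int, int], genotype: GenotypeSpec,
         schedule: InputSchedule) -> BooleanState:
    """One synchronous update, producing the state at time t + 1."""
    J = network.J
    regs = (state.hb, state.Kr, state.pdm, state.cas, state.x)
    nxt = {}
    for i, gene in enumerate(_REGULATED):
        if genotype.gene == gene:
            nxt[gene] = genotype.clamp_value
            continue
        total = int(sum(int(J[i, j]) * regs[j] for j in range(5)))
        if total > 0:
            nxt[gene] = 1
        elif total < 0:
            nxt[gene] = 0
        else:
            nxt[gene] = defaults[i]
    t1 = t + 1
    if genotype.gene == "hb":
        hb = genotype.clamp_value
    else:
        # svp pulse at t=1 drives hb off from t=2; hb has no activator and
        # a zero default, so it never recovers.
        hb = schedule.hb_input(t1)
    return BooleanState(hb=hb, Kr=nxt["Kr"], pdm=nxt["pdm"], cas=nxt["cas"],
                        svp=schedule.svp_input(t1), x=schedule.x_input(t1))


def initial_state(genotype: GenotypeSpec,
                  schedule: InputSchedule) -> BooleanState:
    """t = 0: everything OFF except hb (and x when its polarity starts ON);
    genotype clamps override."""
    hb = 1 if genotype.gene != "hb" else genotype.clamp_value
    st = {"hb": hb, "Kr": 0, "pdm": 0, "cas": 0}
    if genotype.gene in ("Kr", "pdm", "cas"):
        st[genotype.gene] = genotype.clamp_value
    return BooleanState(**st, svp=schedule.svp_input(0),
                        x=schedule.x_input(0))


def simulate(network: SignNetwork, genotype: GenotypeSpec,
             defaults: tuple[int, int, int],
             schedule: InputSchedule) -> BooleanTrajectory:
    state = initial_state(genotype, schedule)
    rows = [state.as_tuple()]
    for t in range(schedule.t_end):
        state = step(state, t, network, defaults, genotype, schedule)
        rows.append(state.as_tuple())
    return BooleanTrajectory(np.array(rows, dtype=np.int8))


def compress(trajectory: BooleanTrajectory) -> tuple[tuple[int, ...], ...]:
    """Ordered distinct consecutive (hb, Kr, pdm, cas) states.

    Durations are dropped; the result is idempotent under re-compression.
    """
    seq = []
    for row in trajectory.states[:, :4]:
        st = tuple(int(v) for v in row)
        if not seq or seq[-1] != st:
            seq.append(st)
    return tuple(seq)
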