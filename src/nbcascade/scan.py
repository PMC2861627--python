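"""Exhaustive Boolean screens over candidate networks.

``scan_known_factors`` enumerates all 3^12 networks of the known genes;
``scan_with_x`` enumerates all 3^15 networks including the hypothetical
early factor x, over every switching time of x.  A network is
*WT-compatible* when some combination of default states (and t_x)
reproduces the wild-type profile, and *functional* when a single
(defaults, t_x) witness reproduces the profiles of all nine genotypes.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels
from .boolean import simulate
from .criteria import all_criteria, criterion_for, matches
from .network import (GENOTYPES, N_NETWORKS_12, N_NETWORKS_15, REGULATORS,
                      TARGETS, GenotypeSpec, InputSchedule, SignNetwork,
                      default_states)

log = logging.getLogger(__name__)

_GENE_IDX = {"hb": 0, "Kr": 1, "pdm": 2, "cas": 3}


def _criteria_arrays():
    """Flatten the JSON criteria into the arrays the kernel consumes."""
    ordered = np.full((9, 4), -1, np.int8)
    strict = np.zeros((9, 3), np.int8)
    persist = np.zeros(9, np.int8)
    clampg = np.full(9, -1, np.int8)
    clampv = np.zeros(9, np.int8)
    for g, spec in enumerate(GENOTYPES):
        crit = criterion_for(spec)
        for k, gene in enumerate(crit.ordered):
            ordered[g, k] = _GENE_IDX[gene]
        for k, (a, b) in enumerate(zip(crit.ordered[:-1], crit.ordered[1:])):
            if (a, b) in crit.strict_pairs:
                strict[g, k] = 1
        persist[g] = 1 if crit.persist else 0
        if not spec.is_wt:
            clampg[g] = _GENE_IDX[spec.gene]
            clampv[g] = spec.clamp_value
    return ordered, strict, persist, clampg, clampv


@dataclass
class ScanReport:
    total: int
    n_wt_compatible: int
    n_functional: int
    t_end: int
    tx_grid: tuple[int, int]
    polarity: str
    rejections_by_genotype: dict[str, int] = field(default_factory=dict)
    elapsed_s: float = 0.0

    def to_dict(self) -> dict:
        return {
            "total": self.total,
            "n_wt_compatible": self.n_wt_compatible,
            "n_functional": self.n_functional,
            "t_end": self.t_end,
            "tx_grid": list(self.tx_grid),
            "polarity": self.polarity,
            "rejections_by_genotype": self.rejections_by_genotype,
            "elapsed_s": round(self.elapsed_s, 2),
        }


@dataclass(frozen=True)
class FunctionalRecord:
    """A functional network together with one witness that certifies it."""
    code: int
    defaults: tuple[int, int, int]
    t_x: int

    @property
    def network(self) -> SignNetwork:
        return SignNetwork.from_code(self.code, include_x=True)


def is_functional(network: SignNetwork, defaults: tuple[int, int, int],
                  schedule: InputSchedule) -> bool:
    """Scalar check: do all nine genotypes match under this witness?"""
    return all(
        matches(simulate(network, g, defaults, schedule), criterion_for(g))
        for g in GENOTYPES
    )


def find_witness(network: SignNetwork, t_end: int = 10,
                 polarity: str = "on_off"):
    """First (defaults, t_x) witness under which the network is functional,
    or None."""
    for defaults in default_states():
        for t_x in range(1, t_end + 1):
            sched = InputSchedule(t_end=t_end, t_x=t_x, x_polarity=polarity)
            if is_functional(network, defaults, sched):
                return defaults, t_x
    return None


def _run_scan(n_slots: int, t_end: int, tx_lo: int, tx_hi: int,
              polarity: str, chunk: int, max_records: int):
    ordered, strict, persist, clampg, clampv = _criteria_arrays()
    pol = 0 if polarity == "on_off" else 1
    total = N_NETWORKS_12 if n_slots == 12 else N_NETWORKS_15
    out_codes = np.zeros(max_records, np.int64)
    out_s0 = np.zeros(max_records, np.int64)
    out_tx = np.zeros(max_records, np.int64)
    tally = np.zeros(9, np.int64)
    n_func = 0
    n_wt = 0
    t0 = time.time()
    for lo in range(0, total, chunk):
        hi = min(lo + chunk, total)
        nf, nw = _kernels.scan_codes(
            lo, hi, n_slots, t_end, tx_lo, tx_hi, pol,
            ordered, strict, persist, clampg, clampv,
            out_codes[n_func:], out_s0[n_func:], out_tx[n_func:], tally)
        n_func += nf
        n_wt += nw
        log.info("scan %d/%d codes: %d functional, %d WT-compatible",
                 hi, total, n_func, n_wt)
    if n_func > max_records:
        raise RuntimeError(f"functional set exceeded buffer ({n_func})")
    records = [
        FunctionalRecord(
            int(out_codes[i]),
            (int(out_s0[i]) & 1, (int(out_s0[i]) >> 1) & 1,
             (int(out_s0[i]) >> 2) & 1),
            int(out_tx[i]))
        for i in range(n_func)
    ]
    report = ScanReport(
        total=total, n_wt_compatible=n_wt, n_functional=n_func,
        t_end=t_end, tx_grid=(tx_lo, tx_hi), polarity=polarity,
        rejections_by_genotype={
            GENOTYPES[g].name: int(tally[g]) for g in range(9) if tally[g]},
        elapsed_s=time.time() - t0,
    )
    return report, records


def scan_known_factors(t_end: int = 10, chunk: int = 3 ** 12) -> ScanReport:
    """The 3^12 screen of networks over hb, Kr, pdm, cas and svp only."""
    report, _ = _run_scan(12, t_end, 1, 1, "on_off", chunk, 4096)
    return report


def scan_with_x(polarity: str = "on_off", t_end: int = 10,
                chunk: int = 3 ** 13,
                ) -> tuple[ScanReport, list[FunctionalRecord]]:
    """The 3^15 screen including factor x, over all switching times t_x."""
    if polarity not in ("on_off", "off_on"):
        raise ValueError(f"bad polarity {polarity!r}")
    return _run_scan(15, t_end, 1, t_end, polarity, chunk, 65536)


def common_regulations(records_or_networks) -> dict[tuple[str, str], object]:
    """Slotwise intersection over a set of networks.

    Returns {(regulator, target): value} where value is the shared sign for
    slots identical across the whole set, or the string ``"varies"``.
    Zero-everywhere slots are reported as 0.
    """
    Js = _as_matrix(records_or_networks)
    if len(Js) == 0:
        raise ValueError("empty network set")
    out = {}
    for i, t in enumerate(TARGETS):
        for j, r in enumerate(REGULATORS):
            col = Js[:, i, j]
            out[(r, t)] = int(col[0]) if (col == col[0]).all() else "varies"
    return out


def functional_records_frame(records) -> pd.DataFrame:
    rows = [{"code": r.code, "s0_Kr": r.defaults[0], "s0_pdm": r.defaults[1],
             "s0_cas": r.defaults[2], "t_x": r.t_x} for r in records]
    return pd.DataFrame(rows)


def _as_matrix(items) -> np.ndarray:
    Js = []
    for it in items:
        if isinstance(it, FunctionalRecord):
            Js.append(it.network.J)
        elif isinstance(it, SignNetwork):
            Js.append(it.J)
        else:
            Js.append(np.asarray(it, dtype=np.int8))
    return np.array(Js, dtype=np.int8)


def kernel_matches(network: SignNetwork, genotype: GenotypeSpec,
                   defaults: tuple[int, int, int],
                   schedule: InputSchedule) -> bool:
    """Vectorized-engine verdict for one case (oracle hook; the scalar
    path is simulate + matches)."""
    ordered, strict, persist, clampg, clampv = _criteria_arrays()
    g = GENOTYPES.index(genotype)
    s0 = defaults[0] | (defaults[1] << 1) | (defaults[2] << 2)
    pol = 0 if schedule.x_polarity == "on_off" else 1
    return bool(_kernels.genotype_ok_single(
        network.J, g, s0, schedule.t_x, pol, schedule.t_end,
        ordered, strict, persist, clampg, clampv))
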