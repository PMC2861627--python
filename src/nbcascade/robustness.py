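"""Monte-Carlo robustness scoring of functional networks.

Robustness is the fraction of trials whose continuous dynamics reproduce
the wild-type sequential profile: under random parameter assignment
(noise-free), or under transcriptional noise given parameter sets that
succeed without noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _sps

from . import _kernels
from .continuous import ContinuousParams
from .network import SignNetwork, TARGETS, REGULATORS, drosophila_network
from .sampling import ParameterRanges, rng_from, sample_parameter_batch
from .stats import distances_to


@dataclass(frozen=True)
class RobustnessResult:
    network_code: int
    kind: str               # "parameter-variation" | "noise"
    n_trials: int
    n_success: int
    sigma: float
    seed: int

    @property
    def fraction(self) -> float:
        return self.n_success / self.n_trials

    def to_dict(self) -> dict:
        return {"network_code": self.network_code, "kind": self.kind,
                "n_trials": self.n_trials, "n_success": self.n_success,
                "fraction": self.fraction, "sigma": self.sigma,
                "seed": self.seed}


def _defaults() -> ContinuousParams:
    return ContinuousParams(strengths=np.zeros((3, 5)), promoters=np.zeros(5))


def _run_batch(Jts, Ss, base: ContinuousParams, sigma: float, seed: int):
    out = np.zeros(len(Jts), np.uint8)
    n = _kernels.mc_wt_success(
        np.ascontiguousarray(Jts), np.ascontiguousarray(Ss),
        base.d_m, base.d_p, base.k_m, base.hill_n, base.t_hb, base.t_x,
        sigma, base.dt, base.t_total, base.p_th, seed & 0x7FFFFFFF, out)
    return n, out


def param_robustness(network: SignNetwork,
                     ranges: ParameterRanges | None = None,
                     n_trials: int = 2000, seed: int = 0,
                     base: ContinuousParams | None = None,
                     ) -> RobustnessResult:
    """Fraction of random parameter sets reproducing the WT profile
    (noise-free)."""
    ranges = ranges or ParameterRanges()
    base = base or _defaults()
    rng = rng_from(seed, "params", network.code)
    Jts, Ss = sample_parameter_batch(network, ranges, rng, n_trials)
    n, _ = _run_batch(Jts, Ss, base, 0.0, seed)
    return RobustnessResult(network.code, "parameter-variation",
                            n_trials, int(n), 0.0, seed)


def harvest_good_params(network: SignNetwork,
                        ranges: ParameterRanges | None = None,
                        n_sets: int = 1000, seed: int = 0,
                        base: ContinuousParams | None = None,
                        batch: int = 5000, max_batches: int = 200):
    """Rejection-sample parameter sets that succeed without noise.

    Returns (strengths (n,3,5), promoters (n,5)).  Raises if the success
    rate is so low (< 1e-4) that the request cannot be met.
    """
    ranges = ranges or ParameterRanges()
    base = base or _defaults()
    rng = rng_from(seed, "harvest", network.code)
    goodJ, goodS = [], []
    total = 0
    for b in range(max_batches):
        Jts, Ss = sample_parameter_batch(network, ranges, rng, batch)
        _, ok = _run_batch(Jts, Ss, base, 0.0, seed + b)
        total += batch
        sel = ok.astype(bool)
        goodJ.append(Jts[sel])
        goodS.append(Ss[sel])
        got = sum(len(a) for a in goodJ)
        if got >= n_sets:
            J = np.concatenate(goodJ)[:n_sets]
            S = np.concatenate(goodS)[:n_sets]
            return J, S
        if total >= 10_000 and got / total < 1e-4:
            break
    raise RuntimeError(
        f"success rate too low for {network!r}: "
        f"{sum(len(a) for a in goodJ)}/{total} noise-free successes")


def noise_robustness(network: SignNetwork, good_params, sigma: float,
                     trials_per_set: int = 50, seed: int = 0,
                     base: ContinuousParams | None = None,
                     verify: bool = True) -> RobustnessResult:
    """Relative success fraction under noise for known-good parameter sets."""
    base = base or _defaults()
    Jts, Ss = good_params
    if verify:
        n0, _ = _run_batch(Jts, Ss, base, 0.0, seed)
        if n0 != len(Jts):
            raise ValueError("good_params contains noise-free failures")
    repJ = np.repeat(Jts, trials_per_set, axis=0)
    repS = np.repeat(Ss, trials_per_set, axis=0)
    n, _ = _run_batch(repJ, repS, base, sigma, seed)
    return RobustnessResult(network.code, "noise", len(repJ), int(n),
                            sigma, seed)


def good_params_summary(network: SignNetwork, good_params) -> pd.DataFrame:
    """Mean and s.d. of each sampled parameter over noise-free successes.

    Tabular replacement for a radar-style display of successful parameter
    sets: one row per nonzero regulation strength and per promoter
    activity.
    """
    Jts, Ss = good_params
    rows = []
    for i, t in enumerate(TARGETS):
        for j, r in enumerate(REGULATORS):
            if network[t, r] == 0:
                continue
            v = Jts[:, i, j]
            rows.append({"parameter": f"J:{r}->{t}", "mean": v.mean(),
                         "sd": v.std(), "n": len(v)})
    for j, g in enumerate(("hb", "Kr", "pdm", "cas", "x")):
        v = Ss[:, j]
        rows.append({"parameter": f"S:{g}", "mean": v.mean(),
                     "sd": v.std(), "n": len(v)})
    return pd.DataFrame(rows)


def knockout(network: SignNetwork, regulation: tuple[str, str]) -> SignNetwork:
    """Remove one (regulator, target) regulation; error if absent."""
    regulator, target = regulation
    if network[target, regulator] == 0:
        raise ValueError(f"regulation {regulator}->{target} absent")
    return network.replace(regulator, target, 0)


@dataclass
class SweepGrid:
    axis1: tuple[str, np.ndarray]
    axis2: tuple[str, np.ndarray]
    fraction: np.ndarray    # shape (len(grid1), len(grid2))

    def to_frame(self) -> pd.DataFrame:
        n1, g1 = self.axis1
        n2, g2 = self.axis2
        rows = []
        for i, v1 in enumerate(g1):
            for j, v2 in enumerate(g2):
                rows.append({n1: v1, n2: v2,
                             "fraction": self.fraction[i, j]})
        return pd.DataFrame(rows)


def _fix_axis(Jts, Ss, name: str, value: float):
    """Pin one swept parameter in a sampled batch.

    Names: ``"J:reg->tgt"`` (signed strength) or ``"S:gene"``.
    """
    if name.startswith("J:"):
        reg, tgt = name[2:].split("->")
        Jts[:, TARGETS.index(tgt), REGULATORS.index(reg)] = value
    elif name.startswith("S:"):
        gene = name[2:]
        Ss[:, ("hb", "Kr", "pdm", "cas", "x").index(gene)] = value
    else:
        raise ValueError(f"bad axis name {name!r}")


def sweep_2d(network: SignNetwork, axis1, axis2,
             n_trials_per_cell: int = 500, seed: int = 0,
             ranges: ParameterRanges | None = None,
             base: ContinuousParams | None = None) -> SweepGrid:
    """Success fraction on a 2-D grid of pinned parameter values; the
    remaining sampled parameters are redrawn per trial."""
    ranges = ranges or ParameterRanges()
    base = base or _defaults()
    name1, grid1 = axis1
    name2, grid2 = axis2
    frac = np.zeros((len(grid1), len(grid2)))
    for i, v1 in enumerate(grid1):
        for j, v2 in enumerate(grid2):
            rng = rng_from(seed, "sweep", network.code, i, j)
            Jts, Ss = sample_parameter_batch(network, ranges, rng,
                                             n_trials_per_cell)
            _fix_axis(Jts, Ss, name1, float(v1))
            _fix_axis(Jts, Ss, name2, float(v2))
            n, _ = _run_batch(Jts, Ss, base, 0.0, seed + 31 * i + j)
            frac[i, j] = n / n_trials_per_cell
    return SweepGrid((name1, np.asarray(grid1, float)),
                     (name2, np.asarray(grid2, float)), frac)


def rank_functional_networks(networks, n_trials: int = 2000, seed: int = 0,
                             ranges: ParameterRanges | None = None,
                             base: ContinuousParams | None = None,
                             ) -> pd.DataFrame:
    """Parameter-variation robustness table for a set of networks.

    Sorted by distance to the *Drosophila* reference, then by fraction
    (descending).  Adds a flag for the reference-architecture rows
    (N_d = 0) and the Spearman correlation between fraction and N_d in
    ``DataFrame.attrs["spearman_rho"]``.
    """
    ref = drosophila_network(include_hb_to_cas=True, include_x=True)
    nets = list(networks)
    nd = distances_to(nets, ref)
    rows = []
    for net, d in zip(nets, nd):
        res = param_robustness(net, ranges, n_trials, seed, base)
        rows.append({"code": net.code, "n_d": int(d),
                     "fraction": res.fraction, "n_trials": n_trials,
                     "is_reference_architecture": int(d) == 0})
    df = pd.DataFrame(rows).sort_values(
        ["n_d", "fraction"], ascending=[True, False]).reset_index(drop=True)
    rho, p = _sps.spearmanr(df["n_d"], df["fraction"])
    df.attrs["spearman_rho"] = float(rho)
    df.attrs["spearman_p"] = float(p)
    return df
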