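"""Continuous transcription-translation dynamics with expression noise.

Each gene i carries an mRNA level M_i and a protein level P_i:

    dM_i/dt = F_i({P_j}) - d_M M_i + sigma_i xi_i(t)
    dP_i/dt = M_i - d_P P_i

with promoter activity F_i = g(S_i(t) + sum_j Jt_ij h(P_j)), where g is
piecewise linear (g(u) = u for u > 0, else 0), h is a Hill saturation
P^n / (K_M^n + P^n), S_i the default promoter activity and Jt the signed
regulation strengths.  hb and x have no regulators; they start at the
expressed steady state of their active promoters, which switch off at
t_hb and t_x, reproducing the imposed pulses of the Boolean model (x is
the earliest factor and switches off first).  Additive white Gaussian
noise acts on transcription only; for hb and x only while their
promoters are active.

Integration is Euler-Maruyama; protein levels are clamped at zero, while
mRNA may fluctuate below zero under noise so that the additive term stays
zero-mean.  A trajectory is accepted as wild type when the protein
levels, discretized at threshold P_th, satisfy the same window criterion
as the Boolean model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import _kernels
from .network import GENOTYPES, GenotypeSpec, SignNetwork
from .sampling import ParameterRanges, sample_parameter_batch

_CGENES = ("hb", "Kr", "pdm", "cas", "x")


@dataclass(frozen=True)
class ContinuousParams:
    """All constants of the continuous model.

    ``strengths`` is the (3, 5) signed regulation-strength matrix for the
    regulated genes (rows Kr, pdm, cas; columns hb, Kr, pdm, cas, x);
    ``promoters`` the default promoter activities (hb, Kr, pdm, cas, x).
    Time units follow the mRNA lifetime (d_M = 1).
    """
    strengths: np.ndarray
    promoters: np.ndarray
    d_m: float = 1.0        # mRNA degradation rate
    d_p: float = 0.2        # protein degradation rate
    k_m: float = 0.1        # Michaelis constant of the promoter Hill term
    hill_n: float = 2.0     # Hill coefficient
    t_hb: float = 10.0      # hb promoter switch-off time
    t_x: float = 5.0        # x promoter switch-off time
    sigma: float = 0.0      # transcriptional noise intensity
    p_th: float = 0.2       # discretization threshold on protein levels
    dt: float = 0.01        # Euler-Maruyama step
    t_total: float = 100.0  # simulated time span
    p_oe: float = 1.0       # clamped protein level for overexpression

    def __post_init__(self):
        J = np.ascontiguousarray(self.strengths, dtype=np.float64)
        S = np.ascontiguousarray(self.promoters, dtype=np.float64)
        if J.shape != (3, 5) or S.shape != (5,):
            raise ValueError("strengths must be (3,5), promoters (5,)")
        if (S < 0).any():
            raise ValueError("promoter activities must be non-negative")
        for name in ("d_m", "d_p", "k_m", "hill_n", "dt", "t_total", "p_th"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        object.__setattr__(self, "strengths", J)
        object.__setattr__(self, "promoters", S)

    def with_(self, **kw) -> "ContinuousParams":
        return replace(self, **kw)


def params_for(network: SignNetwork, ranges: ParameterRanges | None = None,
               rng: np.random.Generator | None = None,
               **overrides) -> ContinuousParams:
    """Randomly assigned parameters for a network (one draw)."""
    ranges = ranges or ParameterRanges()
    rng = rng or np.random.default_rng()
    Jt, S = sample_parameter_batch(network, ranges, rng, 1)
    return ContinuousParams(strengths=Jt[0], promoters=S[0], **overrides)


@dataclass
class ContinuousTrajectory:
    t: np.ndarray
    mrna: np.ndarray        # (n, 5)
    protein: np.ndarray     # (n, 5)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for j, g in enumerate(_CGENES):
            rows.append(pd.DataFrame({
                "t": self.t, "gene": g,
                "M": self.mrna[:, j], "P": self.protein[:, j]}))
        return pd.concat(rows, ignore_index=True)


def promoter_activity(proteins, target: str, params: ContinuousParams,
                      t: float) -> float:
    """F_i for a regulated target, or the gated default promoter of hb/x."""
    P = np.asarray(proteins, dtype=float)
    if target == "hb":
        return float(params.promoters[0]) if t < params.t_hb else 0.0
    if target == "x":
        return float(params.promoters[4]) if t < params.t_x else 0.0
    i = {"Kr": 0, "pdm": 1, "cas": 2}[target]
    h = P ** params.hill_n / (params.k_m ** params.hill_n
                              + P ** params.hill_n)
    h[P <= 0] = 0.0
    total = params.promoters[i + 1] + float(params.strengths[i] @ h)
    return max(total, 0.0)


def integrate(network_or_params, genotype: GenotypeSpec = GenotypeSpec(),
              params: ContinuousParams | None = None,
              seed: int = -1, record_stride: int = 10,
              ) -> ContinuousTrajectory:
    """Integrate the model and record every ``record_stride``-th step.

    With ``sigma == 0`` the dynamics are deterministic and the seed is
    irrelevant; with noise, the same seed reproduces the same path.
    """
    if params is None:
        params = network_or_params     # called with params directly
    p = params
    n_steps = int(round(p.t_total / p.dt))
    n_rec = n_steps // record_stride + 1
    m_out = np.zeros((n_rec, 5))
    p_out = np.zeros((n_rec, 5))
    clamp_gene, clamp_value = -1, 0
    if not genotype.is_wt:
        clamp_gene = _CGENES.index(genotype.gene)
        clamp_value = genotype.clamp_value
    nrec = _kernels.integrate_sde(
        p.strengths, p.promoters, p.d_m, p.d_p, p.k_m, p.hill_n,
        p.t_hb, p.t_x, p.sigma, p.dt, p.t_total,
        clamp_gene, clamp_value, p.p_oe, seed, record_stride, m_out, p_out)
    if not np.isfinite(m_out[:nrec]).all() or not np.isfinite(p_out[:nrec]).all():
        raise FloatingPointError("non-finite state during integration; "
                                 "check dt and parameter magnitudes")
    t = np.arange(nrec) * record_stride * p.dt
    return ContinuousTrajectory(t=t, mrna=m_out[:nrec], protein=p_out[:nrec])


def discretize(trajectory: ContinuousTrajectory, p_th: float) -> np.ndarray:
    """Thresholded (n, 4) ON/OFF matrix for hb, Kr, pdm, cas."""
    if p_th <= 0:
        raise ValueError("p_th must be positive")
    # ties at the threshold map to OFF
    return (trajectory.protein[:, :4] > p_th).astype(np.int8)


def wt_success(network: SignNetwork, params: ContinuousParams,
               seed: int = 0) -> bool:
    """Integrate, discretize and test the wild-type window criterion."""
    Jt = params.strengths[None]
    S = params.promoters[None]
    out = np.zeros(1, np.uint8)
    n = _kernels.mc_wt_success(
        np.ascontiguousarray(Jt), np.ascontiguousarray(S),
        params.d_m, params.d_p, params.k_m, params.hill_n,
        params.t_hb, params.t_x, params.sigma, params.dt, params.t_total,
        params.p_th, int(seed) & 0x7FFFFFFF, out)
    return bool(n)
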