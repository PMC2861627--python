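"""Numba kernels: the vectorized Boolean screen and the SDE integrator.

Scalar reference implementations live in :mod:`nbcascade.boolean` /
:mod:`nbcascade.continuous`; the kernels here are validated against them
in the test suite.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_VAL0, _VAL1, _VAL2 = 0, 1, -5


@njit(cache=True, inline="always")
def _decode_inline(code, n_slots, J):
    c = code
    for tgt in range(3):
        for reg in range(4):
            d = c % 3
            J[tgt, reg] = _VAL0 if d == 0 else (_VAL1 if d == 1 else _VAL2)
            c //= 3
    if n_slots == 15:
        for tgt in range(3):
            d = c % 3
            J[tgt, 4] = _VAL0 if d == 0 else (_VAL1 if d == 1 else _VAL2)
            c //= 3
    else:
        for tgt in range(3):
            J[tgt, 4] = 0


@njit(cache=True, inline="always")
def _genotype_ok(J, g, s0, t_x, pol, t_end,
                 ordered, strict, persist, clampg, clampv):
    """Simulate one genotype and evaluate its profile criterion.

    Gene indices: 0 hb, 1 Kr, 2 pdm, 3 cas.  Windows are spans
    (first ON, last ON); onsets non-decreasing (strict where flagged),
    offsets right-censored at t_end, windows pairwise distinct, final gene
    persistence per criterion.
    """
    cg = clampg[g]
    cv = clampv[g]
    f0 = -1; l0 = -1; n0 = 0
    f1 = -1; l1 = -1; n1 = 0
    f2 = -1; l2 = -1; n2 = 0
    f3 = -1; l3 = -1; n3 = 0
    kr = 0; pdm = 0; cas = 0
    if cg == 1:
        kr = cv
    elif cg == 2:
        pdm = cv
    elif cg == 3:
        cas = cv
    for t in range(t_end + 1):
        if cg == 0:
            hb = cv
        else:
            hb = 1 if t < 2 else 0
        xe = 1 if t < t_x else 0
        x = xe if pol == 0 else 1 - xe
        if hb:
            if f0 < 0:
                f0 = t
            l0 = t; n0 += 1
        if kr:
            if f1 < 0:
                f1 = t
            l1 = t; n1 += 1
        if pdm:
            if f2 < 0:
                f2 = t
            l2 = t; n2 += 1
        if cas:
            if f3 < 0:
                f3 = t
            l3 = t; n3 += 1
        if t == t_end:
            break
        if cg != 1:
            s = J[0, 0] * hb + J[0, 1] * kr + J[0, 2] * pdm \
                + J[0, 3] * cas + J[0, 4] * x
            nkr = 1 if s > 0 else (0 if s < 0 else (s0 & 1))
        else:
            nkr = kr
        if cg != 2:
            s = J[1, 0] * hb + J[1, 1] * kr + J[1, 2] * pdm \
                + J[1, 3] * cas + J[1, 4] * x
            npd = 1 if s > 0 else (0 if s < 0 else ((s0 >> 1) & 1))
        else:
            npd = pdm
        if cg != 3:
            s = J[2, 0] * hb + J[2, 1] * kr + J[2, 2] * pdm \
                + J[2, 3] * cas + J[2, 4] * x
            ncs = 1 if s > 0 else (0 if s < 0 else ((s0 >> 2) & 1))
        else:
            ncs = cas
        kr, pdm, cas = nkr, npd, ncs

    first = (f0, f1, f2, f3)
    last = (l0, l1, l2, l3)
    non = (n0, n1, n2, n3)

    nord = 0
    for k in range(4):
        if ordered[g, k] >= 0:
            nord += 1
    if cg >= 0:
        if cv == 1 and non[cg] != t_end + 1:
            return False
        if cv == 0 and non[cg] != 0:
            return False
    for gg in range(4):
        if gg == cg:
            continue
        listed = False
        for k in range(nord):
            if ordered[g, k] == gg:
                listed = True
        if listed:
            if non[gg] == 0:
                return False
        elif non[gg] != 0:
            return False
    for k in range(nord - 1):
        a = ordered[g, k]
        b = ordered[g, k + 1]
        if strict[g, k]:
            if first[a] >= first[b]:
                return False
        elif first[a] > first[b]:
            return False
        if last[a] != t_end and last[a] > last[b]:
            return False
    if persist[g] and last[ordered[g, nord - 1]] != t_end:
        return False
    for k in range(nord - 1):
        a = ordered[g, k]
        if a == cg:
            continue
        if last[a] == t_end and non[a] == t_end - first[a] + 1:
            return False
    for gg in range(4):
        if non[gg] == 0:
            continue
        for hh in range(gg + 1, 4):
            if non[hh] == 0:
                continue
            if first[gg] == first[hh] and last[gg] == last[hh]:
                return False
    return True


@njit(cache=True)
def scan_codes(code_lo, code_hi, n_slots, t_end, tx_lo, tx_hi, pol,
               ordered, strict, persist, clampg, clampv,
               out_codes, out_s0, out_tx, reject_tally):
    """Screen codes in [code_lo, code_hi).

    Returns (n_functional, n_wt_compatible).  A network is WT-compatible
    if some (defaults, t_x) witness satisfies the wild-type criterion, and
    functional if one witness satisfies all nine genotype criteria.  For a
    WT-compatible, non-functional network the first genotype that fails
    under its first WT witness is tallied in ``reject_tally``.
    """
    nfunc = 0
    nwt = 0
    J = np.zeros((3, 5), np.int8)
    for code in range(code_lo, code_hi):
        _decode_inline(code, n_slots, J)
        wt_seen = False
        func = False
        first_fail = -1
        for s0 in range(8):
            for t_x in range(tx_lo, tx_hi + 1):
                if not _genotype_ok(J, 0, s0, t_x, pol, t_end,
                                    ordered, strict, persist,
                                    clampg, clampv):
                    continue
                if not wt_seen:
                    wt_seen = True
                ok = True
                for g in range(1, 9):
                    if not _genotype_ok(J, g, s0, t_x, pol, t_end,
                                        ordered, strict, persist,
                                        clampg, clampv):
                        ok = False
                        if first_fail < 0:
                            first_fail = g
                        break
                if ok:
                    if nfunc < out_codes.shape[0]:
                        out_codes[nfunc] = code
                        out_s0[nfunc] = s0
                        out_tx[nfunc] = t_x
                    nfunc += 1
                    func = True
                    break
            if func:
                break
        if wt_seen:
            nwt += 1
            if not func and first_fail >= 0:
                reject_tally[first_fail] += 1
    return nfunc, nwt


# ---------------------------------------------------------------------------
# continuous model
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _hill(p, km_n, n):
    if p <= 0.0:
        return 0.0
    h = p * p if n == 2.0 else p ** n
    return h / (km_n + h)


@njit(cache=True, fastmath=True)
def integrate_sde(Jt, S, d_m, d_p, km, hill_n, t_hb, t_x, sigma, dt, t_total,
                  clamp_gene, clamp_value, p_oe, seed, record_stride,
                  m_out, p_out):
    """Euler-Maruyama integration of the transcription-translation model.

    Genes 0 hb, 1 Kr, 2 pdm, 3 cas, 4 x.  ``Jt`` is the (3, 5) strength
    matrix for the regulated genes; hb and x are driven by their default
    promoters only (switched off at t_hb / t_x).  Additive Gaussian noise
    of intensity ``sigma`` enters the mRNA equations; for hb and x only
    while their promoters are active.  Concentrations are clamped at zero.

    Records every ``record_stride``-th step into m_out / p_out (pass
    arrays of length 0 to skip recording).  Returns the number of recorded
    rows.
    """
    if seed >= 0:
        np.random.seed(seed)
    km_n = km * km if hill_n == 2.0 else km ** hill_n
    n_steps = int(round(t_total / dt))
    M = np.zeros(5)
    P = np.zeros(5)
    # hb and x start expressed (steady state of their active promoters)
    M[0] = S[0]
    P[0] = S[0] / d_p
    M[4] = S[4]
    P[4] = S[4] / d_p
    sq = np.sqrt(dt)
    nrec = 0
    record = m_out.shape[0] > 0
    for step_i in range(n_steps + 1):
        t = step_i * dt
        if record and step_i % record_stride == 0 and nrec < m_out.shape[0]:
            for i in range(5):
                m_out[nrec, i] = M[i]
                p_out[nrec, i] = P[i]
            nrec += 1
        if step_i == n_steps:
            break
        s_hb = S[0] if t < t_hb else 0.0
        s_x = S[4] if t < t_x else 0.0
        # promoter activities
        f_hb = s_hb
        f_x = s_x
        f = np.empty(3)
        for i in range(3):
            tot = S[i + 1]
            tot += Jt[i, 0] * _hill(P[0], km_n, hill_n)
            tot += Jt[i, 1] * _hill(P[1], km_n, hill_n)
            tot += Jt[i, 2] * _hill(P[2], km_n, hill_n)
            tot += Jt[i, 3] * _hill(P[3], km_n, hill_n)
            tot += Jt[i, 4] * _hill(P[4], km_n, hill_n)
            f[i] = tot if tot > 0.0 else 0.0
        # mRNA updates (noise on transcription only)
        for i in range(5):
            if i == 0:
                fi = f_hb
                sig = sigma if t < t_hb else 0.0
            elif i == 4:
                fi = f_x
                sig = sigma if t < t_x else 0.0
            else:
                fi = f[i - 1]
                sig = sigma
            dM = (fi - d_m * M[i]) * dt
            if sig > 0.0:
                dM += sig * sq * np.random.normal()
            # mRNA may fluctuate below zero under additive noise (the
            # zero-clamp would rectify the noise and pump silenced genes);
            # protein stays non-negative
            M[i] += dM
            P[i] += (M[i] - d_p * P[i]) * dt
            if P[i] < 0.0:
                P[i] = 0.0
        if clamp_gene >= 0:
            if clamp_value == 0:
                M[clamp_gene] = 0.0
                P[clamp_gene] = 0.0
            else:
                P[clamp_gene] = p_oe
    return nrec


@njit(cache=True, inline="always", fastmath=True)
def _wt_success_inner(Jt, S, d_m, d_p, km, hill_n, t_hb, t_x, sigma, dt,
                      t_total, p_th):
    """Integrate without recording and evaluate the WT window criterion on
    the threshold-discretized protein levels of hb, Kr, pdm, cas."""
    km_n = km * km if hill_n == 2.0 else km ** hill_n
    n_steps = int(round(t_total / dt))
    M = np.zeros(5)
    P = np.zeros(5)
    # hb and x start expressed (steady state of their active promoters)
    M[0] = S[0]
    P[0] = S[0] / d_p
    M[4] = S[4]
    P[4] = S[4] / d_p
    sq = np.sqrt(dt)
    first = np.full(4, -1, np.int64)
    last = np.full(4, -1, np.int64)
    n_on = np.zeros(4, np.int64)
    f = np.empty(3)
    for step_i in range(n_steps + 1):
        t = step_i * dt
        for i in range(4):
            if P[i] > p_th:
                if first[i] < 0:
                    first[i] = step_i
                last[i] = step_i
                n_on[i] += 1
        if step_i == n_steps:
            break
        s_hb = S[0] if t < t_hb else 0.0
        s_x = S[4] if t < t_x else 0.0
        for i in range(3):
            tot = S[i + 1]
            tot += Jt[i, 0] * _hill(P[0], km_n, hill_n)
            tot += Jt[i, 1] * _hill(P[1], km_n, hill_n)
            tot += Jt[i, 2] * _hill(P[2], km_n, hill_n)
            tot += Jt[i, 3] * _hill(P[3], km_n, hill_n)
            tot += Jt[i, 4] * _hill(P[4], km_n, hill_n)
            f[i] = tot if tot > 0.0 else 0.0
        for i in range(5):
            if i == 0:
                fi = s_hb
                sig = sigma if t < t_hb else 0.0
            elif i == 4:
                fi = s_x
                sig = sigma if t < t_x else 0.0
            else:
                fi = f[i - 1]
                sig = sigma
            dM = (fi - d_m * M[i]) * dt
            if sig > 0.0:
                dM += sig * sq * np.random.normal()
            # mRNA may fluctuate below zero under additive noise (the
            # zero-clamp would rectify the noise and pump silenced genes);
            # protein stays non-negative
            M[i] += dM
            P[i] += (M[i] - d_p * P[i]) * dt
            if P[i] < 0.0:
                P[i] = 0.0
    # WT criterion on discretized windows
    for i in range(4):
        if first[i] < 0:
            return False
    for k in range(3):
        if first[k] > first[k + 1]:
            return False
        if last[k] != n_steps and last[k] > last[k + 1]:
            return False
    if last[3] != n_steps:
        return False
    for a in range(3):
        if last[a] == n_steps and n_on[a] == n_steps - first[a] + 1:
            return False
    for a in range(4):
        for b in range(a + 1, 4):
            if first[a] == first[b] and last[a] == last[b]:
                return False
    return True


@njit(cache=True)
def mc_wt_success(Jts, Ss, d_m, d_p, km, hill_n, t_hb, t_x, sigma, dt,
                  t_total, p_th, seed, out):
    """Batch WT-success evaluation over pre-sampled parameter sets.

    Jts: (n, 3, 5), Ss: (n, 5).  out: uint8 per-trial success flags.
    """
    np.random.seed(seed)
    n = Jts.shape[0]
    nsucc = 0
    for k in range(n):
        ok = _wt_success_inner(Jts[k], Ss[k], d_m, d_p, km, hill_n,
                               t_hb, t_x, sigma, dt, t_total, p_th)
        out[k] = 1 if ok else 0
        if ok:
            nsucc += 1
    return nsucc


@njit(cache=True)
def genotype_ok_single(J, g, s0, t_x, pol, t_end,
                       ordered, strict, persist, clampg, clampv):
    """Single (network, genotype, defaults, t_x) check; test hook for the
    scalar-reference equivalence oracle."""
    return _genotype_ok(J, g, s0, t_x, pol, t_end,
                        ordered, strict, persist, clampg, clampv)
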