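"""Independent brute-force reference implementations used as test oracles.

Everything here is deliberately written with plain Python loops,
``math.lgamma`` and dictionaries, sharing no code path with the vectorized
package implementation it checks.
"""

from __future__ import annotations

import math

import numpy as np

COMP = {0: 3, 1: 2, 2: 1, 3: 0, 4: 4}

NORMAL, SNP, EDITED = 0, 1, 2
NOT_EDITED, EF, ER = 0, 1, 2


def _cand_bases(cand, pair):
    """(position, plus-strand base) pairs of a candidate, loop-built."""
    out = []
    for end, seq in ((cand.end1, pair.seq1), (cand.end2, pair.seq2)):
        if end is None:
            continue
        if end.positions is not None:
            for p, b in zip(end.positions, end.bases):
                if b < 4:
                    out.append((int(p), int(b)))
            continue
        if end.strand == 1:
            oriented = [int(b) for b in seq]
        else:
            oriented = [COMP[int(b)] for b in reversed(seq)]
        for t, b in enumerate(oriented):
            if b < 4:
                out.append((end.start + t, b))
    return out


def _cand_gap(cand):
    g = cand.gap_log
    for end in (cand.end1, cand.end2):
        if end is not None:
            g += end.gap_log
    return g


def brute_posteriors(sets, profile_dist, x):
    """Per read, posterior over its candidates: softmax of
    gap + log X_k + sum log G."""
    posts = []
    for cs in sets:
        lls = []
        for cand in cs.candidates:
            ll = _cand_gap(cand) + math.log(x[cand.copy])
            for p, b in _cand_bases(cand, cs.pair):
                ll += math.log(profile_dist[p][b])
            lls.append(ll)
        mx = max(lls)
        ws = [math.exp(v - mx) for v in lls]
        z = sum(ws)
        posts.append([w / z for w in ws])
    return posts


def brute_marginal(sets, profile_dist, x):
    total = 0.0
    for cs in sets:
        lls = []
        for cand in cs.candidates:
            ll = _cand_gap(cand) + math.log(x[cand.copy])
            for p, b in _cand_bases(cand, cs.pair):
                ll += math.log(profile_dist[p][b])
            lls.append(ll)
        mx = max(lls)
        total += mx + math.log(sum(math.exp(v - mx) for v in lls))
    return total


def brute_stats(sets, posts, n, r):
    U = [[0.0] * 4 for _ in range(n)]
    V = [0.0] * r
    gap = 0.0
    for cs, ps in zip(sets, posts):
        for cand, w in zip(cs.candidates, ps):
            V[cand.copy] += w
            gap += w * _cand_gap(cand)
            for p, b in _cand_bases(cand, cs.pair):
                U[p][b] += w
    return U, V, gap


def brute_m_expression(V, alpha_x):
    num = [max(alpha_x - 1.0 + v, 0.0) for v in V]
    s = sum(num)
    if s <= 0:
        return [1.0 / len(V)] * len(V)
    return [v / s for v in num]


def brute_m_profile(u4, alpha4, eps=1e-10):
    num = [max(a - 1.0 + u, eps) for a, u in zip(alpha4, u4)]
    s = sum(num)
    return [v / s for v in num]


def _alpha_for(priors, t, ref):
    if t == NORMAL:
        return [
            priors.alpha_normal_ref if b == ref else priors.alpha_normal_other
            for b in range(4)
        ]
    if t == SNP:
        return [priors.alpha_snp] * 4
    alt = {0: 2, 3: 1}.get(ref)
    if alt is None:
        return None
    return [
        priors.alpha_edited_ref
        if b == ref
        else (priors.alpha_edited_alt if b == alt else priors.alpha_edited_other)
        for b in range(4)
    ]


def _log_beta(alpha):
    return sum(math.lgamma(a) for a in alpha) - math.lgamma(sum(alpha))


def _type_objective(priors, u4, ref, t, editable):
    if t == EDITED and not editable:
        return None
    if editable:
        lp = {
            NORMAL: math.log(1 - priors.p_snp - priors.p_edited),
            SNP: math.log(priors.p_snp),
            EDITED: math.log(priors.p_edited),
        }[t]
    else:
        lp = {NORMAL: math.log(1 - priors.p_snp), SNP: math.log(priors.p_snp)}[t]
    alpha = _alpha_for(priors, t, ref)
    if alpha is None:
        return None
    g = brute_m_profile(u4, alpha)
    obj = lp - _log_beta(alpha)
    for a, u, gi in zip(alpha, u4, g):
        obj += (a - 1.0 + u) * math.log(gi)
    return obj, g


def brute_state_type_profile(U, genome, priors):
    """Exhaustive per-copy state choice, then types and profile rows."""
    n, r = genome.n, genome.r
    ref = [int(b) for b in genome.ref_for_model]
    core = [bool(c) for c in genome.is_core]
    p_ed = priors.p_state_edited
    state_lp = [math.log(1 - 2 * p_ed), math.log(p_ed), math.log(p_ed)]
    states, types, prof = [0] * r, [0] * n, [[0.25] * 4 for _ in range(n)]
    for k in range(r):
        lo, hi = genome.copies[k].local_interval
        best_score, best_state = None, 0
        for st in (NOT_EDITED, EF, ER):
            score = state_lp[st]
            for i in range(lo, hi):
                editable = core[i] and (
                    (st == EF and ref[i] == 0) or (st == ER and ref[i] == 3)
                )
                vals = []
                for t in (NORMAL, SNP, EDITED):
                    res = _type_objective(priors, U[i], ref[i], t, editable)
                    if res is not None:
                        vals.append(res[0])
                score += max(vals)
            # strict >: ties keep the earlier (not_edited-first) state
            if best_score is None or score > best_score:
                best_score, best_state = score, st
        states[k] = best_state
        for i in range(lo, hi):
            st = best_state
            editable = core[i] and (
                (st == EF and ref[i] == 0) or (st == ER and ref[i] == 3)
            )
            best_obj, best_t, best_g = None, NORMAL, None
            for t in (NORMAL, SNP, EDITED):
                res = _type_objective(priors, U[i], ref[i], t, editable)
                if res is None:
                    continue
                if best_obj is None or res[0] > best_obj:
                    best_obj, best_t, best_g = res[0], t, res[1]
            types[i] = best_t
            prof[i] = best_g
    return states, types, prof


def brute_log_prior(profile_dist, types, states, x, priors, genome):
    n, r = genome.n, genome.r
    ref = [int(b) for b in genome.ref_for_model]
    p_ed = priors.p_state_edited
    state_lp = [math.log(1 - 2 * p_ed), math.log(p_ed), math.log(p_ed)]
    total = sum(state_lp[int(s)] for s in states)
    core = [bool(c) for c in genome.is_core]
    for i in range(n):
        k = int(genome.pos_to_copy[i])
        st = int(states[k])
        editable = core[i] and ((st == EF and ref[i] == 0) or (st == ER and ref[i] == 3))
        t = int(types[i])
        if editable:
            lp = [
                math.log(1 - priors.p_snp - priors.p_edited),
                math.log(priors.p_snp),
                math.log(priors.p_edited),
            ][t]
        else:
            if t == EDITED:
                return -math.inf
            lp = [math.log(1 - priors.p_snp), math.log(priors.p_snp)][t]
        total += lp
        alpha = _alpha_for(priors, t, ref[i])
        total -= _log_beta(alpha)
        for a, g in zip(alpha, profile_dist[i]):
            total += (a - 1.0) * math.log(g)
    ax = [priors.alpha_x] * r
    total -= _log_beta(ax)
    for a, xv in zip(ax, x):
        total += (a - 1.0) * math.log(xv)
    return total


def brute_end_placements(genome, seq, max_other_mm):
    """All-offsets scan for ungapped placements of one end (both strands,
    best of both masking modes), for genomes small enough to enumerate."""

    def mask(codes, mode):
        out = []
        for b in codes:
            if mode == "sense" and b == 0:
                out.append(2)
            elif mode == "antisense" and b == 3:
                out.append(1)
            else:
                out.append(b)
        return out

    q = len(seq)
    gseq = [int(b) for b in genome.seq]
    results = {}
    for strand in (1, -1):
        oriented = [int(b) for b in seq] if strand == 1 else [
            COMP[int(b)] for b in reversed(seq)
        ]
        for start in range(genome.n - q + 1):
            k = int(genome.pos_to_copy[start])
            lo, hi = genome.copies[k].local_interval
            if start < lo or start + q > hi:
                continue
            window = gseq[start : start + q]
            best = None
            for mode in ("sense", "antisense"):
                mw = mask(window, mode)
                mr = mask(oriented, mode)
                mm = sum(1 for a, b in zip(mw, mr) if a != b)
                # hidden (editing-compatible) differences
                ag = sum(
                    1
                    for t in range(q)
                    if mw[t] == mr[t] and window[t] != oriented[t]
                )
                cand = (mm, ag, mode)
                if best is None or cand < best:
                    best = cand
            if best[0] <= max_other_mm:
                results[(start, strand)] = best
    return results
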