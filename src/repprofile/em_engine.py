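"""EM over candidate alignments: E-step, closed-form M-steps, restarts.

The E-step computes, for every read independently, a posterior over its
candidate placements,

    P(A_j | R_j, G, X)  ∝  h(A_j) · X_{k(A_j)} · ∏_t G_{A_j(t)}(R_j(t)),

normalized over the candidate set only (the candidate-set approximation to
the intractable sum over all alignments), and accumulates the expected base
counts ``U`` and read counts ``V``.

The M-step is exact and layered: expression ``X`` has a closed-form Dirichlet
MAP update; for each position and each variation type the profile row has a
closed-form MAP ``Ĝ_T``; the type is the argmax of
log P(T|H) − log Z_T + (α_T − 1 + U_i)·log Ĝ_T; and each copy's state is the
argmax of its prior plus the summed best-type objectives, after which types
and profile are fixed by back-substitution.

Because every M-step layer is an exact argmax of the posterior-expected
complete-data objective, each EM step cannot decrease the (candidate-set)
log posterior  log P(θ) + Σ_j log Σ_a P(a, R_j | θ),  which is the quantity
tracked as the objective, used for convergence, and reported as
``Solution.log_joint``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .repeat_model import (
    EDITED_FORWARD,
    EDITED_REVERSE,
    NOT_EDITED,
    TYPE_EDITED,
    TYPE_NORMAL,
    TYPE_SNP,
    BASE_A,
    BASE_T,
    ExpressionVector,
    PositionTypeAssignment,
    PriorConfig,
    Profile,
    RepeatGenome,
    RepeatStateAssignment,
    SufficientStats,
    dirichlet_log_norm,
    prior_mean_profile,
    revcomp,
)

logger = logging.getLogger("repprofile")

PROFILE_EPS = 1e-10  # clip for (alpha - 1 + U) numerators at the boundary


class EMInternalError(RuntimeError):
    """The objective decreased beyond numerical tolerance: an update bug."""


# --------------------------------------------------------------------------
# Candidate compilation
# --------------------------------------------------------------------------


class CompiledCandidates:
    """Flat array view of candidate alignments for vectorized E-steps.

    Base-level entries are (position, plus-strand read base) pairs; bases read
    on the minus strand are complemented so that ``U`` accumulates in
    plus-strand coordinates.  Read ends containing N contribute no likelihood
    at those positions.
    """

    def __init__(self, sets, genome: RepeatGenome, priors: PriorConfig):
        self.genome = genome
        self.sets = [s for s in sets if not s.unalignable]
        cand_read, cand_copy, cand_gap, cand_objs = [], [], [], []
        flat_chunks, cand_nbases = [], []
        for j, cs in enumerate(self.sets):
            for cand in cs.candidates:
                gap = cand.gap_log
                nb = 0
                for end, seq in ((cand.end1, cs.pair.seq1), (cand.end2, cs.pair.seq2)):
                    if end is None:
                        continue
                    gap += end.gap_log
                    if end.positions is not None:
                        pos = end.positions
                        bases = end.bases
                    else:
                        pos = np.arange(end.start, end.start + end.length, dtype=np.int64)
                        bases = seq if end.strand == 1 else revcomp(seq)
                    ok = bases < 4
                    idx = pos[ok] * 4 + bases[ok]
                    flat_chunks.append(idx.astype(np.int64))
                    nb += int(ok.sum())
                cand_read.append(j)
                cand_copy.append(cand.copy)
                cand_gap.append(gap)
                cand_objs.append(cand)
                cand_nbases.append(nb)

        self.m = len(self.sets)
        self.K = len(cand_read)
        self.cand_read = np.asarray(cand_read, dtype=np.int64)
        self.cand_copy = np.asarray(cand_copy, dtype=np.int64)
        self.cand_gap = np.asarray(cand_gap, dtype=np.float64)
        self.cand_objs = cand_objs
        self.flat_idx = (
            np.concatenate(flat_chunks).astype(np.int32)
            if flat_chunks
            else np.empty(0, dtype=np.int32)
        )
        nb = np.asarray(cand_nbases, dtype=np.int64)
        self.cand_of_base = np.repeat(np.arange(self.K, dtype=np.int32), nb)
        self.cand_ptr = np.concatenate([[0], np.cumsum(nb)])
        self.cand_empty = nb == 0
        self.read_ptr = np.zeros(self.m + 1, dtype=np.int64)
        np.add.at(self.read_ptr, self.cand_read + 1, 1)
        self.read_ptr = np.cumsum(self.read_ptr)


# --------------------------------------------------------------------------
# E-step
# --------------------------------------------------------------------------


def e_step(
    compiled: CompiledCandidates,
    profile: Profile,
    expr: ExpressionVector,
    priors: PriorConfig,
):
    """Posterior over candidates per read, sufficient stats, marginal loglik.

    Returns ``(posteriors, stats, marginal_loglik)`` where ``posteriors`` is a
    flat (K,) array aligned with ``compiled.cand_objs`` and
    ``marginal_loglik = Σ_j log Σ_a h(a) X_{k(a)} ∏ G(R_j)`` over reads with at
    least one finite candidate.
    """
    genome = compiled.genome
    log_g = profile.log().ravel()
    log_x = np.log(expr.x)

    per_base = log_g[compiled.flat_idx]
    if compiled.K and len(per_base):
        # contiguous per-candidate segments: reduceat, fixing empty segments
        cand_ll = np.add.reduceat(
            per_base, np.minimum(compiled.cand_ptr[:-1], len(per_base) - 1)
        )
        cand_ll[compiled.cand_empty] = 0.0
    else:
        cand_ll = np.zeros(compiled.K)
    cand_ll += compiled.cand_gap + log_x[compiled.cand_copy]

    mx = np.maximum.reduceat(cand_ll, compiled.read_ptr[:-1])
    finite = np.isfinite(mx)
    if not np.all(finite):
        logger.warning(
            "%d reads had no finite candidate this step; excluded", int((~finite).sum())
        )
    mx_safe = np.where(finite, mx, 0.0)
    w = np.exp(cand_ll - mx_safe[compiled.cand_read])
    w[~finite[compiled.cand_read]] = 0.0
    z = np.bincount(compiled.cand_read, weights=w, minlength=compiled.m)
    z_safe = np.where(z > 0, z, 1.0)
    post = w / z_safe[compiled.cand_read]

    V = np.bincount(compiled.cand_copy, weights=post, minlength=genome.r)
    U = np.bincount(
        compiled.flat_idx,
        weights=post[compiled.cand_of_base],
        minlength=genome.n * 4,
    ).reshape(genome.n, 4)
    gap_exp = float(post @ compiled.cand_gap)
    marginal = float(np.sum(np.log(z_safe[finite]) + mx[finite]))
    return post, SufficientStats(U=U, V=V, gap_logprob=gap_exp), marginal


# --------------------------------------------------------------------------
# M-steps
# --------------------------------------------------------------------------


def m_step_expression(V: np.ndarray, alpha_x: float | np.ndarray) -> ExpressionVector:
    """MAP expression: (α_X − 1 + V) / Σ(α_X − 1 + V), clipped at 0."""
    num = np.maximum(np.asarray(alpha_x, dtype=float) - 1.0 + V, 0.0)
    tot = num.sum()
    if tot <= 0:
        logger.warning("all-zero expression numerator; falling back to uniform")
        return ExpressionVector(np.full(len(V), 1.0 / len(V)))
    return ExpressionVector(num / tot)


def m_step_profile(U: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """MAP profile row(s): (α_T − 1 + U) / Σ(α_T − 1 + U), clipped at ε.

    Accepts a single (4,) count vector with (4,) alpha, or (n, 4) stacks.
    """
    num = np.maximum(alpha - 1.0 + U, PROFILE_EPS)
    return num / num.sum(axis=-1, keepdims=True)


def _type_objectives(U: np.ndarray, genome: RepeatGenome, priors: PriorConfig):
    """Per type, the profile-maximized data objective at every position.

    Returns ``(data, ghat)`` with ``data[t, i] = −log B(α_t) +
    (α_t − 1 + U_i)·log Ĝ_t,i`` and ``ghat[t]`` the (n, 4) MAP profile rows.
    """
    alpha_tab = priors.alpha_table()
    ref = genome.ref_for_model
    data = np.empty((3, genome.n))
    ghat = np.empty((3, genome.n, 4))
    for t in range(3):
        alpha = alpha_tab[t, ref]  # (n, 4)
        coeff = alpha - 1.0 + U
        g = m_step_profile(U, alpha)
        ghat[t] = g
        data[t] = -dirichlet_log_norm(alpha, axis=-1) + (coeff * np.log(g)).sum(axis=-1)
    return data, ghat


def m_step_types(
    U_i: np.ndarray, ref_base: int, state: int, is_core: bool, priors: PriorConfig
) -> tuple[int, np.ndarray]:
    """Best type and its MAP profile row for one position (ties -> normal)."""
    alpha_tab = priors.alpha_table()
    tl = priors.type_log_prior()
    editable = int(is_core and ref_base == {
        EDITED_FORWARD: BASE_A, EDITED_REVERSE: BASE_T
    }.get(state, -1))
    best_t, best_obj, best_row = TYPE_NORMAL, -np.inf, None
    for t in (TYPE_NORMAL, TYPE_SNP, TYPE_EDITED):
        lp = tl[editable, t]
        if not np.isfinite(lp):
            continue
        alpha = alpha_tab[t, ref_base]
        row = m_step_profile(U_i, alpha)
        obj = lp - dirichlet_log_norm(alpha) + ((alpha - 1.0 + U_i) * np.log(row)).sum()
        if obj > best_obj:
            best_t, best_obj, best_row = t, obj, row
    return best_t, best_row


def m_step_states(
    U: np.ndarray, genome: RepeatGenome, priors: PriorConfig
) -> tuple[RepeatStateAssignment, PositionTypeAssignment, Profile]:
    """Joint argmax over (H, T, G): optimal state per copy, then back-
    substituted types and profile.  Ties break toward not_edited / normal."""
    data, ghat = _type_objectives(U, genome, priors)
    tl = priors.type_log_prior()
    state_lp = priors.state_log_prior()

    # per position: best objective when not editable, and when editable
    obj_not = np.maximum(tl[0, TYPE_NORMAL] + data[TYPE_NORMAL], tl[0, TYPE_SNP] + data[TYPE_SNP])
    stack_ed = np.stack(
        [
            tl[1, TYPE_NORMAL] + data[TYPE_NORMAL],
            tl[1, TYPE_SNP] + data[TYPE_SNP],
            tl[1, TYPE_EDITED] + data[TYPE_EDITED],
        ]
    )
    obj_ed = stack_ed.max(axis=0)

    is_a = (genome.seq == BASE_A) & genome.is_core
    is_t = (genome.seq == BASE_T) & genome.is_core
    # per-position objective under each hypothetical copy state
    per_state = np.empty((3, genome.n))
    per_state[NOT_EDITED] = obj_not
    per_state[EDITED_FORWARD] = np.where(is_a, obj_ed, obj_not)
    per_state[EDITED_REVERSE] = np.where(is_t, obj_ed, obj_not)

    starts = np.array([cp.local_interval[0] for cp in genome.copies], dtype=np.int64)
    scores = np.stack(
        [np.add.reduceat(per_state[s], starts) + state_lp[s] for s in range(3)]
    )  # (3, r)
    states = np.argmax(scores, axis=0).astype(np.int8)  # first max -> not_edited

    st_per_pos = states[genome.pos_to_copy]
    editable = ((st_per_pos == EDITED_FORWARD) & is_a) | (
        (st_per_pos == EDITED_REVERSE) & is_t
    )

    # back-substitute types: argmax with first-max tie-break toward normal
    stack_not = np.stack(
        [
            tl[0, TYPE_NORMAL] + data[TYPE_NORMAL],
            tl[0, TYPE_SNP] + data[TYPE_SNP],
            np.full(genome.n, -np.inf),
        ]
    )
    types = np.where(
        editable, np.argmax(stack_ed, axis=0), np.argmax(stack_not, axis=0)
    ).astype(np.int8)
    profile = Profile(ghat[types, np.arange(genome.n)])
    return RepeatStateAssignment(states), PositionTypeAssignment(types), profile


# --------------------------------------------------------------------------
# Objective (prior terms of the log posterior)
# --------------------------------------------------------------------------


def log_prior_terms(
    profile: Profile,
    types: PositionTypeAssignment,
    states: RepeatStateAssignment,
    expr: ExpressionVector,
    priors: PriorConfig,
    genome: RepeatGenome,
) -> float:
    """log P(H) + log P(T|H) + log f(G|T) + log f(X)."""
    log_g = profile.log()
    total = float(priors.state_log_prior()[states.states].sum())
    editable = genome.editable_mask(states.states).astype(np.int8)
    lp_t = priors.type_log_prior()[editable, types.types]
    if np.any(np.isneginf(lp_t)):
        return -np.inf
    total += float(lp_t.sum())
    alpha = priors.alpha_table()[types.types, genome.ref_for_model]
    total += float(-dirichlet_log_norm(alpha).sum() + ((alpha - 1.0) * log_g).sum())
    r = genome.r
    ax = np.full(r, priors.alpha_x)
    total += float(-dirichlet_log_norm(ax) + ((ax - 1.0) * np.log(expr.x)).sum())
    return total


# --------------------------------------------------------------------------
# EM driver
# --------------------------------------------------------------------------


@dataclass
class InitialCondition:
    profile: Profile
    expr: ExpressionVector
    description: str = "default"


@dataclass
class Solution:
    profile: Profile
    types: PositionTypeAssignment
    states: RepeatStateAssignment
    expr: ExpressionVector
    log_joint: float
    n_steps: int
    trace: list[float]
    posteriors: np.ndarray  # flat (K,) aligned with compiled.cand_objs
    stats: SufficientStats
    compiled: CompiledCandidates = field(repr=False, default=None)
    init_description: str = "default"

    def edited_copies(self) -> frozenset[int]:
        return frozenset(int(k) for k in self.states.edited_copies())

    def map_alignments(self):
        """Per read: (candidate, posterior of the MAP candidate, MQ)."""
        c = self.compiled
        out = []
        for j in range(c.m):
            lo, hi = c.read_ptr[j], c.read_ptr[j + 1]
            sl = self.posteriors[lo:hi]
            best = int(np.argmax(sl)) + lo
            p = float(self.posteriors[best])
            out.append((c.cand_objs[best], p, mapping_quality(p)))
        return out


def default_init(genome: RepeatGenome, priors: PriorConfig) -> InitialCondition:
    return InitialCondition(
        profile=prior_mean_profile(genome, priors),
        expr=ExpressionVector(np.full(genome.r, 1.0 / genome.r)),
        description="default",
    )


def em_run(
    compiled: CompiledCandidates,
    genome: RepeatGenome,
    priors: PriorConfig,
    init: InitialCondition | None = None,
    max_steps: int = 200,
    tol: float = 1e-4,
) -> Solution:
    """Run EM to convergence of the candidate-marginal log posterior.

    Deterministic given the initial condition.  Raises
    :class:`EMInternalError` if the objective decreases by more than 1e-6.
    """
    if init is None:
        init = default_init(genome, priors)
    profile, expr = init.profile, init.expr
    types = PositionTypeAssignment(np.zeros(genome.n, dtype=np.int8))
    states = RepeatStateAssignment(np.zeros(genome.r, dtype=np.int8))
    trace: list[float] = []
    prev = -np.inf
    post, stats, marginal = None, None, None
    for step in range(max_steps):
        post, stats, marginal = e_step(compiled, profile, expr, priors)
        lp = marginal + log_prior_terms(profile, types, states, expr, priors, genome)
        trace.append(lp)
        logger.debug(
            "EM step %d: log_joint=%.6f edited_copies=%d",
            step,
            lp,
            int((states.states != NOT_EDITED).sum()),
        )
        if lp < prev - 1e-6:
            raise EMInternalError(
                f"objective decreased at step {step}: {prev!r} -> {lp!r}"
            )
        if step > 0 and abs(lp - prev) < tol:
            break
        prev = lp
        expr = m_step_expression(stats.V, priors.alpha_x)
        states, types, profile = m_step_states(stats.U, genome, priors)
    else:
        # loop exhausted: refresh stats for the final parameters
        post, stats, marginal = e_step(compiled, profile, expr, priors)
        lp = marginal + log_prior_terms(profile, types, states, expr, priors, genome)
        trace.append(lp)
    return Solution(
        profile=profile,
        types=types,
        states=states,
        expr=expr,
        log_joint=trace[-1],
        n_steps=len(trace),
        trace=trace,
        posteriors=post,
        stats=stats,
        compiled=compiled,
        init_description=init.description,
    )


# --------------------------------------------------------------------------
# Restarts and confidence
# --------------------------------------------------------------------------


def restart_schedule(
    base: Solution, genome: RepeatGenome, priors: PriorConfig
) -> list[InitialCondition]:
    """One new initial condition per hyper-edited copy of ``base``: that
    copy's profile rows are reset to the (not-edited) prior mean."""
    inits = []
    prior_rows = prior_mean_profile(genome, priors).dist
    for k in sorted(base.edited_copies()):
        dist = base.profile.dist.copy()
        sl = genome.copy_slice(k)
        dist[sl] = prior_rows[sl]
        inits.append(
            InitialCondition(
                profile=Profile(dist), expr=base.expr, description=f"remove:{k}"
            )
        )
    return inits


def _record_maximum(maxima: list[Solution], sol: Solution, dedup_tol: float = 1e-3):
    """Retain local maxima, deduplicating those with identical edited sets
    within ``dedup_tol`` log-likelihood of each other."""
    for i, m in enumerate(maxima):
        if m.edited_copies() == sol.edited_copies() and abs(
            m.log_joint - sol.log_joint
        ) <= dedup_tol:
            if sol.log_joint > m.log_joint:
                maxima[i] = sol
            return
    maxima.append(sol)


def run_with_restarts(
    compiled: CompiledCandidates,
    genome: RepeatGenome,
    priors: PriorConfig,
    max_steps: int = 200,
    tol: float = 1e-4,
    max_restarts: int = 50,
) -> tuple[Solution, list[Solution]]:
    """Base run plus the remove-one-edited-copy restart schedule.

    At minimum one restart is tried per hyper-edited copy of the best
    solution; the schedule continues while new optima change the hyper-edited
    set.  Returns (global maximum, all retained local maxima).
    """
    best = em_run(compiled, genome, priors, max_steps=max_steps, tol=tol)
    maxima: list[Solution] = [best]
    tried: set[tuple[frozenset, int]] = set()
    n_restarts = 0
    improved = True
    while improved and n_restarts < max_restarts:
        improved = False
        es = best.edited_copies()
        for init in restart_schedule(best, genome, priors):
            k = int(init.description.split(":")[1])
            if (es, k) in tried:
                continue
            tried.add((es, k))
            n_restarts += 1
            sol = em_run(compiled, genome, priors, init=init, max_steps=max_steps, tol=tol)
            _record_maximum(maxima, sol)
            if sol.log_joint > best.log_joint:
                best = sol
                improved = True
                break
            if n_restarts >= max_restarts:
                break
    return best, maxima


def classify_confidence(maxima: list[Solution]) -> dict[int, str]:
    """Tier per hyper-edited copy of the global maximum: ``most_confident``
    if hyper-edited in every retained local maximum, else ``confident``."""
    if not maxima:
        raise ValueError("need at least one solution")
    best = max(maxima, key=lambda s: s.log_joint)
    tiers = {}
    for k in sorted(best.edited_copies()):
        in_all = all(k in m.edited_copies() for m in maxima)
        tiers[k] = "most_confident" if in_all else "confident"
    return tiers


def mapping_quality(posterior: float) -> int:
    """Phred-scaled misalignment probability, capped at 60."""
    if not 0.0 < posterior <= 1.0:
        raise ValueError("posterior must be in (0, 1]")
    err = 1.0 - posterior
    if err <= 1e-6:
        return 60
    return int(min(60, round(-10.0 * np.log10(err))))
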