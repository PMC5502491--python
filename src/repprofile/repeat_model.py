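"""Generative model for reads drawn from a repeat family.

The model treats one repeat family at a time.  Its random variables are

* ``H`` — per repeat copy, a hyper-editing state: not edited, hyper-edited on
  the forward strand (A-to-G in plus-strand coordinates) or on the reverse
  strand (T-to-C in plus-strand coordinates);
* ``T`` — per position, a variation type: normal, SNP or edited.  The edited
  type is only available at reference A in a forward-edited copy (reference T
  in a reverse-edited copy), and only inside the repeat-annotated core;
* ``G`` — per position, the probability of sequencing A/C/G/T (the genome
  profile), drawn from a Dirichlet whose parameters are selected by ``T`` and
  the reference base;
* ``X`` — per copy, the relative expression level: the probability that a read
  originates in that copy, Dirichlet-distributed;
* ``A`` — per read, the (latent) alignment, drawn from ``X`` with an affine
  gap penalty ``h(A)`` for indels;
* ``R`` — the observed read bases, drawn independently per aligned position
  from ``G``.

Reparameterized through the sufficient statistics ``U`` (expected base counts
per position) and ``V`` (expected read counts per copy), the read likelihood
is the exponential family

    P(A, R | G, X)  ∝  h(A) · ∏_k X_k^{V_k} · ∏_{i,x} G_i(x)^{U_i^x}

which makes every M-step update closed-form (see :mod:`repprofile.em_engine`).

Coordinates are 0-based half-open internally; BED input is native 0-based
half-open; SAM output is 1-based.  All arithmetic is in the log domain.
"""

from __future__ import annotations

import configparser
import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

# --------------------------------------------------------------------------
# Alphabet
# --------------------------------------------------------------------------

BASES = "ACGT"
BASE_CHARS = "ACGTN"
BASE_A, BASE_C, BASE_G, BASE_T, BASE_N = 0, 1, 2, 3, 4

COMPLEMENT = np.array([3, 2, 1, 0, 4], dtype=np.uint8)

_ENCODE = np.full(256, BASE_N, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i


def encode_seq(seq: str) -> np.ndarray:
    """Encode a nucleotide string as uint8 codes (A=0, C=1, G=2, T=3, N=4)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode_seq(codes: np.ndarray) -> str:
    lut = np.frombuffer(b"ACGTN", dtype=np.uint8)
    return lut[codes].tobytes().decode("ascii")


def revcomp(codes: np.ndarray) -> np.ndarray:
    return COMPLEMENT[codes[::-1]]


# --------------------------------------------------------------------------
# Discrete states
# --------------------------------------------------------------------------

NOT_EDITED, EDITED_FORWARD, EDITED_REVERSE = 0, 1, 2
STATE_NAMES = ("not_edited", "edited_forward", "edited_reverse")

TYPE_NORMAL, TYPE_SNP, TYPE_EDITED = 0, 1, 2
TYPE_NAMES = ("normal", "snp", "edited")

#: reference base at which the edited type is licensed, per state (-1 = none)
EDITABLE_REF_BASE = {NOT_EDITED: -1, EDITED_FORWARD: BASE_A, EDITED_REVERSE: BASE_T}
#: the base produced by editing, per state
EDITED_ALT_BASE = {EDITED_FORWARD: BASE_G, EDITED_REVERSE: BASE_C}


# --------------------------------------------------------------------------
# Repeat genome
# --------------------------------------------------------------------------


@dataclass
class RepeatCopy:
    """One (merged) repeat interval plus flanks, in repeat-genome coordinates.

    ``core_intervals`` are the repeat-annotated subintervals in *local*
    (repeat-genome) coordinates; everything else inside ``local_interval`` is
    flank.  A copy produced by merging two oppositely-oriented annotated
    intervals (an inverted-repeat duplex) carries both cores.
    """

    id: str
    chrom: str
    source_interval: tuple[int, int]
    strand: str
    local_interval: tuple[int, int]
    core_intervals: list[tuple[int, int]]
    family: str

    def __post_init__(self) -> None:
        lo, hi = self.local_interval
        for cs, ce in self.core_intervals:
            if not (lo <= cs < ce <= hi):
                raise ValueError(
                    f"copy {self.id}: core interval ({cs},{ce}) outside local "
                    f"interval ({lo},{hi})"
                )

    @property
    def length(self) -> int:
        return self.local_interval[1] - self.local_interval[0]

    def local_to_source(self, pos: int) -> int:
        """Map a local (repeat-genome) position back to the reference."""
        return self.source_interval[0] + (pos - self.local_interval[0])


class RepeatGenome:
    """Concatenation of all copies of one repeat family plus flanks.

    Positions partition exactly into the copies' local intervals; ``n`` is the
    total number of positions and ``r`` the number of copies.
    """

    def __init__(self, seq: np.ndarray, copies: list[RepeatCopy], family: str):
        seq = np.asarray(seq, dtype=np.uint8)
        expected = 0
        pos_to_copy = np.empty(len(seq), dtype=np.int32)
        is_core = np.zeros(len(seq), dtype=bool)
        for k, cp in enumerate(copies):
            lo, hi = cp.local_interval
            if lo != expected:
                raise ValueError("copy intervals must be contiguous from 0")
            expected = hi
            pos_to_copy[lo:hi] = k
            for cs, ce in cp.core_intervals:
                is_core[cs:ce] = True
        if expected != len(seq):
            raise ValueError("copy intervals do not cover the sequence")
        self.seq = seq
        self.copies = copies
        self.family = family
        self.pos_to_copy = pos_to_copy
        self.is_core = is_core
        # model reference: N squashed to A for Dirichlet table lookups only
        self.ref_for_model = np.minimum(seq, 3)

    @property
    def n(self) -> int:
        return len(self.seq)

    @property
    def r(self) -> int:
        return len(self.copies)

    def copy_slice(self, k: int) -> slice:
        lo, hi = self.copies[k].local_interval
        return slice(lo, hi)

    def editable_mask(self, states: np.ndarray) -> np.ndarray:
        """Per position, whether the edited type is licensed under ``states``."""
        st = states[self.pos_to_copy]
        fwd = (st == EDITED_FORWARD) & (self.seq == BASE_A)
        rev = (st == EDITED_REVERSE) & (self.seq == BASE_T)
        return (fwd | rev) & self.is_core


# --------------------------------------------------------------------------
# Parameter containers
# --------------------------------------------------------------------------


@dataclass
class Profile:
    """Per-position categorical distribution over {A, C, G, T}."""

    dist: np.ndarray  # (n, 4) float64

    def validate(self, atol: float = 1e-9) -> None:
        if self.dist.ndim != 2 or self.dist.shape[1] != 4:
            raise ValueError("profile must be (n, 4)")
        if not np.all(self.dist > 0):
            raise ValueError("profile entries must be strictly positive")
        if not np.allclose(self.dist.sum(axis=1), 1.0, atol=atol):
            raise ValueError("profile rows must sum to 1")

    def log(self) -> np.ndarray:
        return np.log(self.dist)


@dataclass
class PositionTypeAssignment:
    types: np.ndarray  # (n,) int8 in {TYPE_NORMAL, TYPE_SNP, TYPE_EDITED}


@dataclass
class RepeatStateAssignment:
    states: np.ndarray  # (r,) int8 in {NOT_EDITED, EDITED_FORWARD, EDITED_REVERSE}

    def edited_copies(self) -> np.ndarray:
        return np.flatnonzero(self.states != NOT_EDITED)


@dataclass
class ExpressionVector:
    x: np.ndarray  # (r,) float64, sums to 1

    def validate(self, atol: float = 1e-9) -> None:
        if np.any(self.x < 0) or abs(self.x.sum() - 1.0) > atol:
            raise ValueError("expression must be a probability vector")


@dataclass
class SufficientStats:
    """Expected base counts per position (U) and read counts per copy (V)."""

    U: np.ndarray  # (n, 4) float64
    V: np.ndarray  # (r,) float64
    gap_logprob: float = 0.0  # E[log h(A)] over the alignment posterior


# --------------------------------------------------------------------------
# Priors
# --------------------------------------------------------------------------


@dataclass
class PriorConfig:
    """Dirichlet and categorical hyperparameters of the generative model.

    The Dirichlet 4-vectors are parameterized per variation type and reference
    base.  The *normal* type models a position whose only variation is read
    error: its Dirichlet is 1000 pseudo-observations of the 0.997/0.001
    error profile, i.e. (997, 1, 1, 1) with 997 on the reference base.  The
    *SNP* type is flat (the alternate base and its frequency are unknown a
    priori).  The *edited* type places one extra pseudo-observation on the
    reference and on the edited base (G at reference A forward, C at
    reference T reverse), leaving the editing level nearly uniform.
    ``gap_open``/``gap_extend`` are log-probabilities making up the affine gap
    penalty h(A); ``unpaired_penalty`` is the log-penalty applied to a
    candidate whose mate could not be placed consistently.
    """

    alpha_x: float = 1.0
    alpha_normal_ref: float = 997.0
    alpha_normal_other: float = 1.0
    alpha_snp: float = 1.0
    alpha_edited_ref: float = 2.0
    alpha_edited_alt: float = 2.0
    alpha_edited_other: float = 1.0
    p_snp: float = 0.01
    p_edited: float = 0.5
    p_state_edited: float = 0.05
    gap_open: float = -9.2
    gap_extend: float = -2.3
    unpaired_penalty: float = -9.2

    # ---- derived tables -------------------------------------------------

    def alpha_table(self) -> np.ndarray:
        """(type, ref_base, 4) Dirichlet parameters.

        Edited rows are defined for reference A (alt G) and reference T
        (alt C); at other reference bases the edited type is never licensed
        and the row is filled with the normal-type parameters as a harmless
        placeholder.
        """
        tab = np.empty((3, 4, 4), dtype=np.float64)
        for b in range(4):
            row = np.full(4, self.alpha_normal_other)
            row[b] = self.alpha_normal_ref
            tab[TYPE_NORMAL, b] = row
            tab[TYPE_SNP, b] = np.full(4, self.alpha_snp)
            tab[TYPE_EDITED, b] = row  # placeholder, overwritten below
        for ref, alt in ((BASE_A, BASE_G), (BASE_T, BASE_C)):
            row = np.full(4, self.alpha_edited_other)
            row[ref] = self.alpha_edited_ref
            row[alt] = self.alpha_edited_alt
            tab[TYPE_EDITED, ref] = row
        return tab

    def state_log_prior(self) -> np.ndarray:
        p = self.p_state_edited
        return np.log(np.array([1.0 - 2.0 * p, p, p]))

    def type_log_prior(self) -> np.ndarray:
        """(2, 3) log P(T | position context).

        Row 0: position not editable under its copy's state; row 1: editable.
        P(edited | not editable) = 0 (−inf in log space).
        """
        tab = np.full((2, 3), -np.inf)
        tab[0, TYPE_NORMAL] = np.log(1.0 - self.p_snp)
        tab[0, TYPE_SNP] = np.log(self.p_snp)
        tab[1, TYPE_NORMAL] = np.log(1.0 - self.p_snp - self.p_edited)
        tab[1, TYPE_SNP] = np.log(self.p_snp)
        tab[1, TYPE_EDITED] = np.log(self.p_edited)
        return tab

    def validate(self) -> None:
        for name in (
            "alpha_x", "alpha_normal_ref", "alpha_normal_other", "alpha_snp",
            "alpha_edited_ref", "alpha_edited_alt", "alpha_edited_other",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 < self.p_snp + self.p_edited < 1:
            raise ValueError("p_snp + p_edited must lie in (0, 1)")
        if not 0 < 2 * self.p_state_edited < 1:
            raise ValueError("state prior must be a proper distribution")

    # ---- serialization (flat INI-style key/value file) ------------------

    def to_file(self, path) -> None:
        cfg = configparser.ConfigParser()
        cfg["priors"] = {
            f.name: repr(getattr(self, f.name)) for f in dataclasses.fields(self)
        }
        with open(path, "w") as fh:
            cfg.write(fh)

    @classmethod
    def from_file(cls, path) -> "PriorConfig":
        cfg = configparser.ConfigParser()
        with open(path) as fh:
            cfg.read_file(fh)
        kwargs = {k: float(v) for k, v in cfg["priors"].items()}
        out = cls(**kwargs)
        out.validate()
        return out


# --------------------------------------------------------------------------
# Joint log-probability
# --------------------------------------------------------------------------


def dirichlet_log_norm(alpha: np.ndarray, axis: int = -1) -> np.ndarray:
    """log of the Dirichlet normalization constant B(alpha)."""
    return gammaln(alpha).sum(axis=axis) - gammaln(alpha.sum(axis=axis))


def prior_mean_profile(genome: RepeatGenome, priors: PriorConfig) -> Profile:
    """All-normal prior-predictive profile (Dirichlet mean per position).

    Used as the EM starting point: it is strictly positive everywhere so every
    candidate alignment starts with a finite log-probability.
    """
    alpha = priors.alpha_table()[TYPE_NORMAL, genome.ref_for_model]
    return Profile(alpha / alpha.sum(axis=1, keepdims=True))


def log_joint(
    profile: Profile,
    types: PositionTypeAssignment,
    states: RepeatStateAssignment,
    expr: ExpressionVector,
    stats: SufficientStats,
    priors: PriorConfig,
    genome: RepeatGenome,
) -> float:
    """Exponential-family joint log-probability, up to an additive constant.

    Returns log P(H) + log P(T|H) + log f(G|T) + log f(X) plus the
    expected-complete-data likelihood U·log G + V·log X + E[log h(A)], with
    ``U``/``V`` taken from ``stats``.  A type assignment with zero prior
    probability (edited at a non-licensed position) yields −inf.
    """
    n, r = genome.n, genome.r
    if profile.dist.shape != (n, 4):
        raise ValueError("profile/genome dimension mismatch")
    if stats.U.shape != (n, 4) or stats.V.shape != (r,):
        raise ValueError("stats/genome dimension mismatch")
    if types.types.shape != (n,) or states.states.shape != (r,):
        raise ValueError("assignment/genome dimension mismatch")

    log_g = profile.log()
    log_x = np.log(expr.x)

    total = float(priors.state_log_prior()[states.states].sum())

    editable = genome.editable_mask(states.states).astype(np.int8)
    lp_t = priors.type_log_prior()[editable, types.types]
    if np.any(np.isneginf(lp_t)):
        return -np.inf
    total += float(lp_t.sum())

    alpha = priors.alpha_table()[types.types, genome.ref_for_model]
    total += float(-dirichlet_log_norm(alpha).sum() + ((alpha - 1.0) * log_g).sum())

    ax = np.full(r, priors.alpha_x)
    total += float(-dirichlet_log_norm(ax) + ((ax - 1.0) * log_x).sum())

    total += float((stats.U * log_g).sum() + stats.V @ log_x + stats.gap_logprob)
    return total
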