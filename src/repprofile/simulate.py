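"""Simulators for hyper-editing in repeat families.

Three designs are supported:

1. ``make_hypothetical_family`` — a hypothetical family of 24 identical
   copies of one random 1 kb core sequence, 12 per orientation: 20 isolated
   copies each flanked by 1 kb of random sequence, and two inverted-repeat
   duplexes (core followed immediately by its reverse complement), each
   flanked by 1 kb of random sequence.  One duplex is hyper-edited on the
   plus strand, the other on the minus strand.
2. ``simulate_random_hyperediting`` — each editable copy of a supplied repeat
   genome is independently hyper-edited with probability 0.3 in its
   transcription direction; replicated (default 20 times) and pooled.
3. ``simulate_profile_from_table`` — editing levels imposed from an external
   per-position table (emulating levels estimated from cloned sequences).

Profile generation follows one scheme throughout: an editable position is
edited with probability 0.5; an edited position puts probability ``p``
(uniform on [0.001, 0.997]) on the edited base, ``0.998 − p`` on the
reference base and 0.001 on each other base; every repeat-core position has a
0.01 chance of being a SNP with the same level scheme on a uniformly chosen
alternate base; all other positions, including flanks, put 0.997 on the
reference base and 0.001 elsewhere.

Reads are 2x100 bp inner-oriented pairs with uniform insert length (default
200–500), constant Q40 qualities, fragment copy drawn from the expression
weights and offset uniform within the copy; bases are drawn independently
from the profile, so the 0.001 mass doubles as read error.  All randomness
derives from a single master seed via ``numpy.random.SeedSequence`` spawning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .candidates import ReadPair
from .repeat_model import (
    BASE_A,
    BASE_C,
    BASE_G,
    BASE_T,
    EDITED_ALT_BASE,
    EDITED_FORWARD,
    EDITED_REVERSE,
    NOT_EDITED,
    Profile,
    RepeatGenome,
    RepeatStateAssignment,
    decode_seq,
    encode_seq,
    revcomp,
)

FAMILY_NAME = "HYP1"


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Documented sub-seed derivation: SeedSequence(seed).spawn(n)."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


# --------------------------------------------------------------------------
# Truth bookkeeping
# --------------------------------------------------------------------------


@dataclass
class TruthTable:
    """Ground truth of one simulated dataset.

    ``variants`` has columns (position, kind, level, alt_base) in repeat-
    genome coordinates; ``placements`` has one row per simulated pair with
    the true copy, end starts/strands and fragment strand, filled by
    :func:`simulate_reads`.
    """

    states: np.ndarray
    variants: pd.DataFrame
    placements: pd.DataFrame | None = None

    def edited_sites(self) -> np.ndarray:
        return self.variants.loc[self.variants["kind"] == "edited", "position"].to_numpy()

    def edited_levels(self) -> pd.Series:
        ed = self.variants[self.variants["kind"] == "edited"]
        return pd.Series(ed["level"].to_numpy(), index=ed["position"].to_numpy())


# --------------------------------------------------------------------------
# Hypothetical repeat family
# --------------------------------------------------------------------------


@dataclass
class FamilyLayout:
    family: str
    chrom: str
    core_len: int
    duplex_spans: list[tuple[int, int]]  # reference coords of [core+core'] blocks
    duplex_states: list[int]  # intended state per duplex


def _random_seq(rng, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length).astype(np.uint8)


def make_hypothetical_family(
    seed,
    core_len: int = 1000,
    flank_len: int = 1000,
    n_isolated_per_strand: int = 10,
    spacer: int = 200,
) -> tuple[dict[str, str], list[tuple[str, int, int, str, str]], FamilyLayout]:
    """Reference FASTA dict, BED6 rows and layout for the hypothetical family.

    24 identical cores (12 per orientation): ``2 × n_isolated_per_strand``
    isolated copies with random flanks, plus two inverted-repeat duplexes.
    Deterministic per seed; distinct seeds give different flanks but the same
    structure.
    """
    rng = _rng(seed)
    core = _random_seq(rng, core_len)
    core_rc = revcomp(core)

    parts: list[np.ndarray] = []
    bed: list[tuple[str, int, int, str, str]] = []
    chrom = "chrSim"
    pos = 0

    def emit(arr: np.ndarray):
        nonlocal pos
        parts.append(arr)
        pos += len(arr)

    for strand, seq in (("+", core), ("-", core_rc)):
        for _ in range(n_isolated_per_strand):
            emit(_random_seq(rng, flank_len))
            bed.append((chrom, pos, pos + core_len, FAMILY_NAME, strand))
            emit(seq)
            emit(_random_seq(rng, flank_len))
            emit(_random_seq(rng, spacer))

    duplex_spans = []
    for d in range(2):
        emit(_random_seq(rng, flank_len))
        span_start = pos
        bed.append((chrom, pos, pos + core_len, FAMILY_NAME, "+"))
        emit(core)
        bed.append((chrom, pos, pos + core_len, FAMILY_NAME, "-"))
        emit(core_rc)
        duplex_spans.append((span_start, pos))
        emit(_random_seq(rng, flank_len))
        if d == 0:
            emit(_random_seq(rng, spacer))

    reference = {chrom: decode_seq(np.concatenate(parts))}
    layout = FamilyLayout(
        family=FAMILY_NAME,
        chrom=chrom,
        core_len=core_len,
        duplex_spans=duplex_spans,
        duplex_states=[EDITED_FORWARD, EDITED_REVERSE],
    )
    return reference, bed, layout


def truth_states(genome: RepeatGenome, layout: FamilyLayout) -> RepeatStateAssignment:
    """True per-copy states: duplex 1 edited forward, duplex 2 edited reverse."""
    states = np.zeros(genome.r, dtype=np.int8)
    for (span_lo, span_hi), st in zip(layout.duplex_spans, layout.duplex_states):
        for k, cp in enumerate(genome.copies):
            lo, hi = cp.source_interval
            if cp.chrom == layout.chrom and lo <= span_lo and span_hi <= hi:
                states[k] = st
    return RepeatStateAssignment(states)


def duplex_core_positions(genome: RepeatGenome, layout: FamilyLayout) -> np.ndarray:
    """Repeat-genome positions inside the duplex cores (flanks excluded)."""
    out = []
    for span_lo, span_hi in layout.duplex_spans:
        for cp in genome.copies:
            lo, hi = cp.source_interval
            if cp.chrom == layout.chrom and lo <= span_lo and span_hi <= hi:
                off = cp.local_interval[0] - lo
                out.append(np.arange(span_lo + off, span_hi + off))
    return np.concatenate(out) if out else np.empty(0, dtype=np.int64)


# --------------------------------------------------------------------------
# Profile simulation
# --------------------------------------------------------------------------


def simulate_profile(
    genome: RepeatGenome,
    states: RepeatStateAssignment,
    seed,
    p_edit_site: float = 0.5,
    p_snp: float = 0.01,
    level_range: tuple[float, float] = (0.001, 0.997),
    err: float = 0.001,
) -> tuple[Profile, TruthTable]:
    """Draw a genome profile under the stated per-position scheme."""
    rng = _rng(seed)
    n = genome.n
    ref = genome.ref_for_model
    dist = np.full((n, 4), err)
    dist[np.arange(n), ref] = 1.0 - 3 * err  # 0.997 on the reference base

    rows = []

    editable = genome.editable_mask(states.states)
    edited = editable & (rng.random(n) < p_edit_site)
    ed_pos = np.flatnonzero(edited)
    lv = rng.uniform(*level_range, size=ed_pos.size)
    st_per_pos = states.states[genome.pos_to_copy]
    for pos, p in zip(ed_pos, lv):
        alt = EDITED_ALT_BASE[int(st_per_pos[pos])]
        dist[pos] = err
        dist[pos, ref[pos]] = (1.0 - 2 * err) - p
        dist[pos, alt] = p
        rows.append((int(pos), "edited", float(p), alt))

    snp_candidates = genome.is_core & ~edited
    snps = snp_candidates & (rng.random(n) < p_snp)
    sn_pos = np.flatnonzero(snps)
    sn_lv = rng.uniform(*level_range, size=sn_pos.size)
    for pos, p in zip(sn_pos, sn_lv):
        alts = [b for b in range(4) if b != ref[pos]]
        alt = int(rng.choice(alts))
        dist[pos] = err
        dist[pos, ref[pos]] = (1.0 - 2 * err) - p
        dist[pos, alt] = p
        rows.append((int(pos), "snp", float(p), alt))

    variants = pd.DataFrame(rows, columns=["position", "kind", "level", "alt_base"])
    return Profile(dist), TruthTable(states=states.states.copy(), variants=variants)


def simulate_profile_from_table(
    genome: RepeatGenome,
    levels: pd.DataFrame,
    err: float = 0.001,
) -> tuple[Profile, TruthTable]:
    """Profile with editing levels imposed from an external table.

    ``levels`` needs columns (position, level, alt_base); everywhere else the
    profile matches the reference with ``err`` read error.
    """
    n = genome.n
    ref = genome.ref_for_model
    dist = np.full((n, 4), err)
    dist[np.arange(n), ref] = 1.0 - 3 * err
    rows = []
    for pos, p, alt in levels[["position", "level", "alt_base"]].itertuples(index=False):
        pos, alt = int(pos), int(alt)
        dist[pos] = err
        dist[pos, ref[pos]] = (1.0 - 2 * err) - float(p)
        dist[pos, alt] = float(p)
        rows.append((pos, "edited", float(p), alt))
    variants = pd.DataFrame(rows, columns=["position", "kind", "level", "alt_base"])
    return Profile(dist), TruthTable(
        states=np.zeros(genome.r, dtype=np.int8), variants=variants
    )


# --------------------------------------------------------------------------
# Read simulation
# --------------------------------------------------------------------------


def simulate_reads(
    genome: RepeatGenome,
    profile: Profile,
    n_reads: int = 50_000,
    weights: np.ndarray | None = None,
    read_len: int = 100,
    insert_range: tuple[int, int] = (200, 500),
    quality: int = 40,
    seed=0,
) -> tuple[list[ReadPair], pd.DataFrame]:
    """Draw inner-oriented 2x``read_len`` pairs from the profile.

    Returns the pairs and a placements table (pair index, copy, end starts,
    end strands, fragment strand) in repeat-genome coordinates.
    """
    rng = _rng(seed)
    r = genome.r
    if weights is None:
        weights = np.full(r, 1.0 / r)
    weights = np.asarray(weights, dtype=float)
    weights = weights / weights.sum()
    lens = np.array([cp.length for cp in genome.copies])
    starts_of_copy = np.array([cp.local_interval[0] for cp in genome.copies])
    lo_ins, hi_ins = insert_range
    if np.any(lens < max(hi_ins, read_len)):
        hi_ins = int(min(hi_ins, lens.min()))

    copy_k = rng.choice(r, size=n_reads, p=weights)
    inserts = rng.integers(max(lo_ins, read_len), hi_ins + 1, size=n_reads)
    offs = (rng.random(n_reads) * (lens[copy_k] - inserts + 1)).astype(np.int64)
    frag_start = starts_of_copy[copy_k] + offs
    frag_strand = np.where(rng.random(n_reads) < 0.5, 1, -1)

    w1 = frag_start[:, None] + np.arange(read_len)[None, :]
    w2 = (frag_start + inserts - read_len)[:, None] + np.arange(read_len)[None, :]
    all_pos = np.concatenate([w1, w2], axis=1)  # (n, 2q)
    probs = profile.dist[all_pos.ravel()]
    u = rng.random(probs.shape[0])
    drawn = (u[:, None] > probs.cumsum(axis=1)).sum(axis=1).astype(np.uint8)
    drawn = drawn.reshape(n_reads, 2 * read_len)
    b1, b2 = drawn[:, :read_len], drawn[:, read_len:]

    qual = np.full(read_len, quality, dtype=np.int16)
    pairs: list[ReadPair] = []
    rows = []
    for i in range(n_reads):
        if frag_strand[i] == 1:
            s1, s2 = b1[i], revcomp(b2[i])
            st1, st2 = 1, -1
            p1, p2 = w1[i, 0], w2[i, 0]
        else:
            s1, s2 = revcomp(b2[i]), b1[i]
            st1, st2 = -1, 1
            p1, p2 = w2[i, 0], w1[i, 0]
        pairs.append(ReadPair(f"sim{i}", s1.copy(), s2.copy(), qual.copy(), qual.copy()))
        rows.append((f"sim{i}", int(copy_k[i]), int(p1), st1, int(p2), st2, int(frag_strand[i])))
    placements = pd.DataFrame(
        rows,
        columns=["read_id", "copy", "start1", "strand1", "start2", "strand2", "frag_strand"],
    )
    return pairs, placements


def write_fastq_pairs(path1, path2, pairs: list[ReadPair]) -> None:
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for p in pairs:
            f1.write(
                f"@{p.id}/1\n{decode_seq(p.seq1)}\n+\n"
                + "".join(chr(q + 33) for q in p.qual1)
                + "\n"
            )
            f2.write(
                f"@{p.id}/2\n{decode_seq(p.seq2)}\n+\n"
                + "".join(chr(q + 33) for q in p.qual2)
                + "\n"
            )


# --------------------------------------------------------------------------
# Full designs
# --------------------------------------------------------------------------


@dataclass
class SimulatedDataset:
    genome: RepeatGenome
    layout: FamilyLayout | None
    profile: Profile
    truth: TruthTable
    pairs: list[ReadPair]


def simulate_hypothetical_dataset(
    seed: int, n_reads: int = 50_000, **family_kwargs
) -> SimulatedDataset:
    """End-to-end hypothetical-family dataset: genome, profile, reads, truth."""
    from .candidates import build_repeat_genome

    rng_fam, rng_prof, rng_reads = spawn_rngs(seed, 3)
    reference, bed, layout = make_hypothetical_family(rng_fam, **family_kwargs)
    genome = build_repeat_genome(reference, bed, FAMILY_NAME, flank=1000)
    states = truth_states(genome, layout)
    profile, truth = simulate_profile(genome, states, rng_prof)
    pairs, placements = simulate_reads(genome, profile, n_reads=n_reads, seed=rng_reads)
    truth.placements = placements
    return SimulatedDataset(genome, layout, profile, truth, pairs)


def simulate_random_hyperediting(
    genome: RepeatGenome,
    editable_copies: list[int],
    copy_directions: dict[int, int] | None = None,
    p_edit_copy: float = 0.3,
    n_replicates: int = 20,
    n_reads: int = 10_000,
    weights: np.ndarray | None = None,
    seed: int = 0,
) -> list[SimulatedDataset]:
    """Random hyper-editing design: each editable copy is hyper-edited with
    probability ``p_edit_copy`` in its transcription direction; independent
    replicates are returned for pooling."""
    if not editable_copies:
        raise ValueError("editable copy list is empty")
    if copy_directions is None:
        copy_directions = {
            k: (EDITED_REVERSE if genome.copies[k].strand == "-" else EDITED_FORWARD)
            for k in editable_copies
        }
    out = []
    for rng in spawn_rngs(seed, n_replicates):
        states = np.zeros(genome.r, dtype=np.int8)
        for k in editable_copies:
            if rng.random() < p_edit_copy:
                states[k] = copy_directions[k]
        sa = RepeatStateAssignment(states)
        profile, truth = simulate_profile(genome, sa, rng)
        pairs, placements = simulate_reads(
            genome, profile, n_reads=n_reads, weights=weights, seed=rng
        )
        truth.placements = placements
        out.append(SimulatedDataset(genome, None, profile, truth, pairs))
    return out
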