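"""Repeat-genome construction and candidate-alignment enumeration.

Reads originating in long double-stranded RNA can carry an unbounded number of
A-to-G changes (inosine is sequenced as G), so candidate placements are found
on a *masked* three-letter alphabet: A is replaced by G (sense mask) or T by C
(antisense mask) in both read and genome, which hides editing-compatible
mismatches.  Any number of hidden A-to-G (or T-to-C) differences is allowed;
at most ``max_other_mm`` other mismatches survive the mask (default 4).

The internal matcher is seed-and-extend on the masked alphabet with
non-overlapping seeds of length ceil(q / (max_other_mm + 1)), which is
pigeonhole-complete for ungapped placements.  Gapped placements can be
supplied through the SAM import path instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import ceil

import numpy as np

from .repeat_model import (
    BASE_A,
    BASE_C,
    BASE_G,
    BASE_T,
    RepeatCopy,
    RepeatGenome,
    encode_seq,
    decode_seq,
    revcomp,
)

logger = logging.getLogger("repprofile")

SENSE, ANTISENSE = "sense", "antisense"


# --------------------------------------------------------------------------
# Masking
# --------------------------------------------------------------------------


def mask_codes(codes: np.ndarray, mode: str) -> np.ndarray:
    """Mask encoded sequence: sense replaces A with G, antisense T with C."""
    out = codes.copy()
    if mode == SENSE:
        out[out == BASE_A] = BASE_G
    elif mode == ANTISENSE:
        out[out == BASE_T] = BASE_C
    else:
        raise ValueError(f"unknown masking mode: {mode!r}")
    return out


def mask_sequence(seq: str, mode: str) -> str:
    """String-level masking; bases other than A (sense) / T (antisense) and
    anything outside {A,C,G,T} are unchanged."""
    if mode == SENSE:
        return seq.replace("A", "G").replace("a", "g")
    if mode == ANTISENSE:
        return seq.replace("T", "C").replace("t", "c")
    raise ValueError(f"unknown masking mode: {mode!r}")


# --------------------------------------------------------------------------
# Annotation and reference I/O
# --------------------------------------------------------------------------


class BedParseError(ValueError):
    pass


def read_bed(path) -> list[tuple[str, int, int, str, str]]:
    """Parse a BED6 file into (chrom, start, end, name, strand) records.

    The name column holds the repeat family; score is ignored.  Malformed
    lines raise :class:`BedParseError` carrying the 1-based line number.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise BedParseError(f"{path}:{lineno}: expected >=4 BED columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start < 0 or end <= start:
                raise BedParseError(f"{path}:{lineno}: invalid interval [{start},{end})")
            strand = parts[5] if len(parts) >= 6 else "+"
            rows.append((parts[0], start, end, parts[3], strand))
    return rows


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, records: dict[str, str], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# --------------------------------------------------------------------------
# Family grouping and repeat-genome construction
# --------------------------------------------------------------------------


def merge_prefix_families(family_names) -> list[list[str]]:
    """Group family names when one is a string prefix of another.

    e.g. {PROTOP, PROTOP_A, PROTOP_B} form one group.  Grouping is the
    transitive closure of the prefix relation.
    """
    names = sorted(set(family_names))
    parent = {n: n for n in names}

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    # sorted order puts prefixes immediately before their extensions, but a
    # name may extend a non-adjacent shorter name; check all shorter names.
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            if b.startswith(a):
                union(a, b)
            else:
                break  # sorted: no later name can start with a either? not true
    # second pass for safety on non-adjacent prefixes (e.g. AB, ABC, ABD)
    for a in names:
        for b in names:
            if a != b and b.startswith(a):
                union(a, b)
    groups: dict[str, list[str]] = {}
    for n in names:
        groups.setdefault(find(n), []).append(n)
    return [sorted(g) for g in sorted(groups.values())]


class EmptyGenomeError(ValueError):
    pass


def build_repeat_genome(
    reference: dict[str, str] | str,
    annotation: list | str,
    family: str | list[str],
    flank: int = 1000,
) -> RepeatGenome:
    """Build the repeat genome for one family (or prefix-merged family group).

    Each annotated interval is extended by ``flank`` on both sides, clipped at
    chromosome ends; overlapping extended intervals are merged into a single
    copy (oppositely-oriented adjacent cores thus become one duplex copy).
    """
    if isinstance(reference, str):
        reference = read_fasta(reference)
    if isinstance(annotation, str):
        annotation = read_bed(annotation)
    fam_names = {family} if isinstance(family, str) else set(family)
    fam_label = "+".join(sorted(fam_names))

    cores_by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for chrom, start, end, name, strand in annotation:
        if name not in fam_names:
            continue
        if chrom not in reference:
            raise ValueError(f"annotation chromosome {chrom!r} not in reference")
        if end > len(reference[chrom]):
            raise ValueError(
                f"interval [{start},{end}) exceeds {chrom} length {len(reference[chrom])}"
            )
        cores_by_chrom.setdefault(chrom, []).append((start, end, strand))
    if not cores_by_chrom:
        raise EmptyGenomeError(f"no annotated intervals for family {fam_label!r}")

    copies: list[RepeatCopy] = []
    seqs: list[np.ndarray] = []
    offset = 0
    for chrom in sorted(cores_by_chrom):
        cores = sorted(cores_by_chrom[chrom])
        chrom_len = len(reference[chrom])
        clusters: list[list[tuple[int, int, str]]] = []
        cur: list[tuple[int, int, str]] = []
        cur_hi = -1
        for cs, ce, cstrand in cores:
            lo = max(0, cs - flank)
            hi = min(chrom_len, ce + flank)
            if cur and lo < cur_hi:
                cur.append((cs, ce, cstrand))
                cur_hi = max(cur_hi, hi)
            else:
                if cur:
                    clusters.append(cur)
                cur = [(cs, ce, cstrand)]
                cur_hi = hi
        if cur:
            clusters.append(cur)
        for cluster in clusters:
            lo = max(0, min(cs for cs, _, _ in cluster) - flank)
            hi = min(len(reference[chrom]), max(ce for _, ce, _ in cluster) + flank)
            strands = {s for _, _, s in cluster}
            strand = strands.pop() if len(strands) == 1 else "."
            local = (offset, offset + (hi - lo))
            copies.append(
                RepeatCopy(
                    id=f"{fam_label}|{chrom}:{lo}-{hi}",
                    chrom=chrom,
                    source_interval=(lo, hi),
                    strand=strand,
                    local_interval=local,
                    core_intervals=[
                        (offset + (cs - lo), offset + (ce - lo)) for cs, ce, _ in cluster
                    ],
                    family=fam_label,
                )
            )
            seqs.append(encode_seq(reference[chrom][lo:hi]))
            offset += hi - lo
    return RepeatGenome(np.concatenate(seqs), copies, fam_label)


# --------------------------------------------------------------------------
# Reads
# --------------------------------------------------------------------------


@dataclass
class ReadPair:
    id: str
    seq1: np.ndarray  # uint8 codes
    seq2: np.ndarray
    qual1: np.ndarray  # Phred integers
    qual2: np.ndarray

    def mean_quality(self) -> tuple[float, float]:
        return float(self.qual1.mean()), float(self.qual2.mean())


def read_fastq_pairs(path1, path2) -> list[ReadPair]:
    from Bio import SeqIO

    pairs = []
    it1 = SeqIO.parse(str(path1), "fastq")
    it2 = SeqIO.parse(str(path2), "fastq")
    for rec1, rec2 in zip(it1, it2, strict=True):
        pairs.append(
            ReadPair(
                id=rec1.id.removesuffix("/1"),
                seq1=encode_seq(str(rec1.seq)),
                seq2=encode_seq(str(rec2.seq)),
                qual1=np.asarray(rec1.letter_annotations["phred_quality"], dtype=np.int16),
                qual2=np.asarray(rec2.letter_annotations["phred_quality"], dtype=np.int16),
            )
        )
    return pairs


def filter_reads(pairs, min_mean_quality: float = 30.0, on_missing: str = "fail"):
    """Retain a pair iff both ends have mean Phred quality >= threshold.

    ``on_missing`` controls behaviour when a read has no qualities: "fail"
    raises, "pass" keeps the pair.
    """
    kept = []
    for p in pairs:
        if p.qual1.size == 0 or p.qual2.size == 0:
            if on_missing == "fail":
                raise ValueError(f"read pair {p.id} has missing base qualities")
            if on_missing == "pass":
                kept.append(p)
                continue
            raise ValueError(f"unknown on_missing policy {on_missing!r}")
        m1, m2 = p.mean_quality()
        if m1 >= min_mean_quality and m2 >= min_mean_quality:
            kept.append(p)
    return kept


# --------------------------------------------------------------------------
# Candidate alignments
# --------------------------------------------------------------------------


@dataclass
class EndPlacement:
    """Ungapped placement of one read end, in plus-strand genome coordinates.

    ``strand`` is +1 when the read aligns as given, -1 when its reverse
    complement does; ``positions`` is only set for gapped (imported)
    placements, otherwise positions are start..start+q-1.
    """

    start: int
    strand: int
    length: int
    n_AG: int
    n_other: int
    mask_mode: str
    positions: np.ndarray | None = None
    bases: np.ndarray | None = None  # explicit plus-strand read bases (imports)
    gap_log: float = 0.0  # affine gap log-penalty for this end


@dataclass
class CandidateAlignment:
    copy: int
    end1: EndPlacement | None
    end2: EndPlacement | None
    gap_log: float = 0.0

    @property
    def n_AG(self) -> int:
        return sum(e.n_AG for e in (self.end1, self.end2) if e is not None)

    @property
    def n_other(self) -> int:
        return sum(e.n_other for e in (self.end1, self.end2) if e is not None)

    def key(self) -> tuple:
        def ek(e):
            return None if e is None else (e.start, e.strand)

        return (self.copy, ek(self.end1), ek(self.end2))


@dataclass
class CandidateAlignmentSet:
    pair: ReadPair
    candidates: list[CandidateAlignment] = field(default_factory=list)

    @property
    def unalignable(self) -> bool:
        return len(self.candidates) == 0


@dataclass
class PairingRule:
    """Proper pairs: opposite strands, inward orientation, bounded insert."""

    min_insert: int | None = None  # default: max end length
    max_insert: int = 1500


class CandidateEnumerator:
    """Seed-and-extend matcher over the masked repeat genome."""

    def __init__(
        self,
        genome: RepeatGenome,
        max_other_mm: int = 4,
        max_candidates: int = 10_000,
        pairing: PairingRule | None = None,
        pairing_penalty: float = -9.2,
    ):
        self.genome = genome
        self.max_other_mm = max_other_mm
        self.max_candidates = max_candidates
        self.pairing = pairing or PairingRule()
        self.pairing_penalty = pairing_penalty
        self.masked = {
            SENSE: mask_codes(genome.seq, SENSE),
            ANTISENSE: mask_codes(genome.seq, ANTISENSE),
        }
        self._indexes: dict[tuple[str, int], dict[bytes, np.ndarray]] = {}
        # copy index of the copy containing each position (for bounds checks)
        self._copy_start = np.array(
            [cp.local_interval[0] for cp in genome.copies], dtype=np.int64
        )
        self._copy_end = np.array(
            [cp.local_interval[1] for cp in genome.copies], dtype=np.int64
        )

    # ---- k-mer index ----------------------------------------------------

    def _index(self, mode: str, seed_len: int) -> dict[bytes, np.ndarray]:
        key = (mode, seed_len)
        if key not in self._indexes:
            g = self.masked[mode]
            hits: dict[bytes, list[int]] = {}
            buf = g.tobytes()
            for i in range(len(g) - seed_len + 1):
                hits.setdefault(buf[i : i + seed_len], []).append(i)
            self._indexes[key] = {
                k: np.asarray(v, dtype=np.int64) for k, v in hits.items()
            }
        return self._indexes[key]

    # ---- single-end placement -------------------------------------------

    def _end_placements(self, seq: np.ndarray) -> dict[tuple[int, int], EndPlacement]:
        """All ungapped placements of one end with <= max_other_mm masked
        mismatches, keyed by (start, strand); best masking mode retained."""
        q = len(seq)
        n_seeds = self.max_other_mm + 1
        # non-overlapping seeds (pigeonhole-complete for ungapped placements);
        # reads too short for disjoint seeds fall back to a full scan
        seed_len = q // n_seeds
        full_scan = seed_len < 1
        offsets = [] if full_scan else [i * seed_len for i in range(n_seeds)]
        out: dict[tuple[int, int], EndPlacement] = {}
        for strand, oriented in ((1, seq), (-1, revcomp(seq))):
            starts: set[int] = set()
            per_mode_masked = {}
            for mode in (SENSE, ANTISENSE):
                mseq = mask_codes(oriented, mode)
                per_mode_masked[mode] = mseq
                if full_scan:
                    starts.update(range(self.genome.n - q + 1))
                    continue
                index = self._index(mode, seed_len)
                buf = mseq.tobytes()
                for off in offsets:
                    for p in index.get(buf[off : off + seed_len], ()):
                        s = int(p) - off
                        if s >= 0:
                            starts.add(s)
            if not starts:
                continue
            sarr = np.fromiter(starts, dtype=np.int64)
            # placement must lie within a single copy
            k = self.genome.pos_to_copy[np.minimum(sarr, self.genome.n - 1)]
            ok = (sarr + q <= self._copy_end[k]) & (sarr >= self._copy_start[k])
            sarr = sarr[ok]
            if sarr.size == 0:
                continue
            win_idx = sarr[:, None] + np.arange(q)[None, :]
            raw = self.genome.seq[win_idx]
            diff_raw = raw != oriented[None, :]
            best_mm = None
            best_ag = None
            best_mode = None
            for mode in (SENSE, ANTISENSE):
                w = self.masked[mode][win_idx]
                mm = (w != per_mode_masked[mode][None, :]).sum(axis=1)
                ag = (diff_raw & (w == per_mode_masked[mode][None, :])).sum(axis=1)
                if best_mm is None:
                    best_mm, best_ag = mm, ag
                    best_mode = np.zeros(len(sarr), dtype=np.int8)
                else:
                    better = (mm < best_mm) | ((mm == best_mm) & (ag < best_ag))
                    best_mm = np.where(better, mm, best_mm)
                    best_ag = np.where(better, ag, best_ag)
                    best_mode = np.where(better, 1, best_mode)
            keep = best_mm <= self.max_other_mm
            for s, mm, ag, md in zip(
                sarr[keep], best_mm[keep], best_ag[keep], best_mode[keep]
            ):
                out[(int(s), strand)] = EndPlacement(
                    start=int(s),
                    strand=strand,
                    length=q,
                    n_AG=int(ag),
                    n_other=int(mm),
                    mask_mode=ANTISENSE if md else SENSE,
                )
        return out

    # ---- pairing ---------------------------------------------------------

    def _pair_up(
        self, p1: dict, p2: dict, q1: int, q2: int
    ) -> list[CandidateAlignment]:
        rule = self.pairing
        min_ins = rule.min_insert if rule.min_insert is not None else max(q1, q2)
        cands = []
        for (s1, st1), e1 in p1.items():
            for (s2, st2), e2 in p2.items():
                if st1 == st2:
                    continue
                k1 = int(self.genome.pos_to_copy[s1])
                k2 = int(self.genome.pos_to_copy[s2])
                if k1 != k2:
                    continue
                if st1 == 1:  # fragment on + strand: end1 fwd, end2 rev, inward
                    insert = (s2 + q2) - s1
                    ordered = s2 >= s1
                else:  # fragment on - strand
                    insert = (s1 + q1) - s2
                    ordered = s1 >= s2
                if ordered and min_ins <= insert <= rule.max_insert:
                    cands.append(CandidateAlignment(copy=k1, end1=e1, end2=e2))
        return cands

    def enumerate(self, pair: ReadPair) -> CandidateAlignmentSet:
        p1 = self._end_placements(pair.seq1)
        p2 = self._end_placements(pair.seq2)
        cands = self._pair_up(p1, p2, len(pair.seq1), len(pair.seq2))
        if not cands:
            # fall back to single-end candidates with a pairing penalty
            for e in p1.values():
                cands.append(
                    CandidateAlignment(
                        copy=int(self.genome.pos_to_copy[e.start]),
                        end1=e,
                        end2=None,
                        gap_log=self.pairing_penalty,
                    )
                )
            for e in p2.values():
                cands.append(
                    CandidateAlignment(
                        copy=int(self.genome.pos_to_copy[e.start]),
                        end1=None,
                        end2=e,
                        gap_log=self.pairing_penalty,
                    )
                )
        cands.sort(key=lambda c: (c.n_other, c.n_AG, c.key()))
        return CandidateAlignmentSet(pair, cands[: self.max_candidates])

    def enumerate_all(self, pairs) -> tuple[list[CandidateAlignmentSet], int]:
        """Enumerate candidates for many pairs; returns (aligned sets,
        number of unalignable pairs)."""
        sets, dropped = [], 0
        for p in pairs:
            cs = self.enumerate(p)
            if cs.unalignable:
                dropped += 1
            else:
                sets.append(cs)
        if dropped:
            logger.info("%d read pairs had no candidate alignment", dropped)
        return sets, dropped


def enumerate_candidates(
    pair: ReadPair,
    genome: RepeatGenome,
    max_other_mm: int = 4,
    max_candidates: int = 10_000,
    pairing: PairingRule | None = None,
) -> CandidateAlignmentSet:
    """One-shot convenience wrapper around :class:`CandidateEnumerator`."""
    return CandidateEnumerator(
        genome, max_other_mm=max_other_mm, max_candidates=max_candidates, pairing=pairing
    ).enumerate(pair)


# --------------------------------------------------------------------------
# SAM import / export
# --------------------------------------------------------------------------


def _classify_mismatches(
    genome: RepeatGenome, positions: np.ndarray, bases: np.ndarray
) -> tuple[int, int, str]:
    """Count editing-compatible vs other mismatches of plus-strand read bases
    against the unmasked genome; the masking mode minimizing the other-mismatch
    count is chosen."""
    ref = genome.seq[positions]
    diff = ref != bases
    ag = diff & (ref == BASE_A) & (bases == BASE_G)
    tc = diff & (ref == BASE_T) & (bases == BASE_C)
    n_diff = int(diff.sum())
    if ag.sum() >= tc.sum():
        return int(ag.sum()), n_diff - int(ag.sum()), SENSE
    return int(tc.sum()), n_diff - int(tc.sum()), ANTISENSE


def import_candidates_sam(
    path, genome: RepeatGenome, max_other_mm: int = 4, pairing: PairingRule | None = None
) -> list[CandidateAlignmentSet]:
    """Collate name-grouped SAM/BAM records into candidate sets.

    Contigs must be copy ids of ``genome`` (unmappable contigs are skipped
    with a warning); mismatch classes are recomputed against the unmasked
    genome and records exceeding ``max_other_mm`` non-editing mismatches are
    dropped.  Input must be grouped by read name.
    """
    import pysam

    contig_to_copy = {cp.id: k for k, cp in enumerate(genome.copies)}
    rule = pairing or PairingRule()
    seen: set[str] = set()
    sets: list[CandidateAlignmentSet] = []

    def flush(name, ends):
        placements = ({}, {})
        lengths = [0, 0]
        seqs = [None, None]
        quals = [None, None]
        for which, copy_k, e, seq, qual in ends:
            placements[which][(e.start, e.strand)] = e
            lengths[which] = max(lengths[which], e.length)
            if seqs[which] is None:
                seqs[which], quals[which] = seq, qual
        pair = ReadPair(
            id=name,
            seq1=seqs[0] if seqs[0] is not None else np.empty(0, np.uint8),
            seq2=seqs[1] if seqs[1] is not None else np.empty(0, np.uint8),
            qual1=quals[0] if quals[0] is not None else np.empty(0, np.int16),
            qual2=quals[1] if quals[1] is not None else np.empty(0, np.int16),
        )
        # re-key placements by global start for pairing
        p1 = {k: v for k, v in placements[0].items()}
        p2 = {k: v for k, v in placements[1].items()}
        enum = CandidateEnumerator(genome, max_other_mm=max_other_mm, pairing=rule)
        cands = enum._pair_up(p1, p2, lengths[0] or 1, lengths[1] or 1)
        if not cands:
            for pd, which in ((p1, 0), (p2, 1)):
                for (start, strand), e in pd.items():
                    cands.append(
                        CandidateAlignment(
                            copy=int(genome.pos_to_copy[start]),
                            end1=e if which == 0 else None,
                            end2=e if which == 1 else None,
                            gap_log=enum.pairing_penalty,
                        )
                    )
        sets.append(CandidateAlignmentSet(pair, cands))

    current = None
    bucket: list = []
    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                continue
            if rec.query_name != current:
                if current is not None:
                    if current in seen:
                        raise ValueError("SAM input is not grouped by read name")
                    seen.add(current)
                    flush(current, bucket)
                current, bucket = rec.query_name, []
            if rec.reference_name not in contig_to_copy:
                logger.warning("skipping record on unknown contig %s", rec.reference_name)
                continue
            k = contig_to_copy[rec.reference_name]
            cp = genome.copies[k]
            qseq = rec.query_sequence
            if qseq is None:
                continue  # secondary without sequence: cannot re-verify
            codes = encode_seq(qseq)
            # pysam reports SEQ already on the contig plus strand
            ap = [(qp, rp) for qp, rp in rec.get_aligned_pairs() if qp is not None and rp is not None]
            if not ap:
                continue
            qpos = np.array([a[0] for a in ap])
            rpos = np.array([a[1] for a in ap]) + cp.local_interval[0]
            bases = codes[qpos]
            n_ag, n_other, mmode = _classify_mismatches(genome, rpos, bases)
            if n_other > max_other_mm:
                continue
            gap_log = sum(
                -9.2 + -2.3 * (ln - 1)
                for op, ln in (rec.cigartuples or [])
                if op in (1, 2)
            )
            placement = EndPlacement(
                start=int(rec.reference_start) + cp.local_interval[0],
                strand=-1 if rec.is_reverse else 1,
                length=len(ap),
                n_AG=n_ag,
                n_other=n_other,
                mask_mode=mmode,
                positions=rpos,
                bases=bases,
                gap_log=float(gap_log),
            )
            which = 1 if rec.is_read2 else 0
            q = rec.query_qualities
            bucket.append(
                (
                    which,
                    k,
                    placement,
                    codes,
                    np.asarray(q, dtype=np.int16) if q is not None else np.empty(0, np.int16),
                )
            )
        if current is not None:
            if current in seen:
                raise ValueError("SAM input is not grouped by read name")
            flush(current, bucket)
    return sets


def export_candidates_sam(path, genome: RepeatGenome, sets, posteriors=None, mqs=None):
    """Write candidate (or final) alignments as SAM, one contig per copy.

    Optional per-set ``posteriors``/``mqs`` annotate the MAP candidate with
    the ZP (posterior) and MAPQ fields; the custom "ag" tag carries the
    editing-compatible mismatch count.
    """
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unsorted", "GO": "query"},
        "SQ": [
            {"SN": cp.id, "LN": cp.length} for cp in genome.copies
        ],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for si, cs in enumerate(sets):
            post = posteriors[si] if posteriors is not None else None
            for ci, cand in enumerate(cs.candidates):
                for which, end, seq, qual in (
                    (0, cand.end1, cs.pair.seq1, cs.pair.qual1),
                    (1, cand.end2, cs.pair.seq2, cs.pair.qual2),
                ):
                    if end is None:
                        continue
                    cp = genome.copies[cand.copy]
                    a = pysam.AlignedSegment()
                    a.query_name = cs.pair.id
                    oriented = seq if end.strand == 1 else revcomp(seq)
                    a.query_sequence = decode_seq(oriented)
                    a.flag = (
                        0x1
                        | (0x40 if which == 0 else 0x80)
                        | (0x10 if end.strand == -1 else 0)
                        | (0x100 if ci > 0 else 0)
                    )
                    a.reference_id = cand.copy
                    a.reference_start = end.start - cp.local_interval[0]
                    a.mapping_quality = int(mqs[si]) if (mqs is not None and ci == 0) else 0
                    a.cigarstring = f"{end.length}M"
                    if qual.size:
                        a.query_qualities = pysam.qualitystring_to_array(
                            "".join(chr(q + 33) for q in qual)
                        )
                    tags = [("NM", end.n_AG + end.n_other), ("ag", end.n_AG)]
                    if post is not None:
                        tags.append(("ZP", float(post[ci])))
                    a.tags = tags
                    out.write(a)
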