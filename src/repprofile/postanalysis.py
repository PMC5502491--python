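"""Edit-site calling, accuracy metrics and editing-pattern statistics.

Pattern analyses mirror how hyper-editing behaves in double-stranded RNA:

* runs of consecutively edited adenosines are treated as censored lifetime
  data — a run terminated by a non-adenosine (or the read end) might have
  continued, so only runs terminated by an *unedited* adenosine are observed
  deaths.  The discrete hazard P(run length = n | length >= n) is estimated
  as  #(n long, uncensored) / (#(n long, uncensored) + #(> n long));
* editing level as a function of the three-letter sequence context around the
  edited adenosine (centered and 3'-anchored framings), compared pairwise by
  Welch t-tests with Benjamini–Hochberg–Yekutieli FDR control;
* helix length from secondary structure, merging stacked base pairs across
  interior bulges of up to two bases on one or both sides, and editing
  frequency binned by helix length.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .repeat_model import (
    BASE_A,
    BASE_CHARS,
    BASE_G,
    COMPLEMENT,
    EDITED_ALT_BASE,
    EDITED_FORWARD,
    EDITED_REVERSE,
    NOT_EDITED,
    TYPE_EDITED,
    RepeatGenome,
    decode_seq,
)


# --------------------------------------------------------------------------
# Edit-site calling and accuracy
# --------------------------------------------------------------------------


def call_edit_sites(
    solution,
    genome: RepeatGenome,
    min_coverage: float = 1.0,
    min_level: float = 0.01,
    tiers: dict[int, str] | None = None,
) -> pd.DataFrame:
    """Table of positions typed as edited, with level and expected coverage.

    The editing level is the profile probability of the edited base (G for a
    forward-edited copy, C for reverse).  Thresholds are inclusive.  Source
    coordinates are 0-based.
    """
    types = solution.types.types
    states = solution.states.states
    coverage = solution.stats.U.sum(axis=1)
    rows = []
    for pos in np.flatnonzero(types == TYPE_EDITED):
        k = int(genome.pos_to_copy[pos])
        st = int(states[k])
        if st == NOT_EDITED:
            continue
        alt = EDITED_ALT_BASE[st]
        level = float(solution.profile.dist[pos, alt])
        cov = float(coverage[pos])
        if level < min_level or cov < min_coverage:
            continue
        cp = genome.copies[k]
        rows.append(
            {
                "position": int(pos),
                "chrom": cp.chrom,
                "source_pos": cp.local_to_source(int(pos)),
                "copy": k,
                "copy_id": cp.id,
                "ref_base": BASE_CHARS[genome.seq[pos]],
                "alt_base": BASE_CHARS[alt],
                "strand": "+" if st == EDITED_FORWARD else "-",
                "level": level,
                "coverage": cov,
                "tier": (tiers or {}).get(k, "confident"),
            }
        )
    cols = [
        "position", "chrom", "source_pos", "copy", "copy_id", "ref_base",
        "alt_base", "strand", "level", "coverage", "tier",
    ]
    return pd.DataFrame(rows, columns=cols)


def sensitivity_ppv(predicted, true) -> tuple[float, float]:
    """(sensitivity, PPV) of predicted vs true position sets.

    Empty denominators yield NaN (undefined).
    """
    pred, tru = set(predicted), set(true)
    tp = len(pred & tru)
    sens = tp / len(tru) if tru else float("nan")
    ppv = tp / len(pred) if pred else float("nan")
    return sens, ppv


def editing_level_comparison(predicted, true) -> tuple[pd.DataFrame, float, float]:
    """Pair predicted and simulated levels over the union of edited sites.

    Sites absent on one side contribute 0 on that side.  Returns the paired
    table, the least-squares slope through the origin and the RMSE.
    """
    predicted = dict(predicted)
    true = dict(true)
    pos = sorted(set(predicted) | set(true))
    x = np.array([true.get(p, 0.0) for p in pos])
    y = np.array([predicted.get(p, 0.0) for p in pos])
    pairs = pd.DataFrame({"position": pos, "true_level": x, "predicted_level": y})
    sxx = float(x @ x)
    slope = float(x @ y) / sxx if sxx > 0 else float("nan")
    rmse = float(np.sqrt(np.mean((y - x) ** 2))) if len(pos) else float("nan")
    return pairs, slope, rmse


# --------------------------------------------------------------------------
# Censored run lengths
# --------------------------------------------------------------------------


def extract_runs(ref_bases: np.ndarray, read_bases: np.ndarray) -> list[tuple[int, bool]]:
    """Maximal stretches of consecutive reference-A positions read as G.

    Inputs are strand-normalized (the edited base is G at reference A) and
    equal length.  A run is censored iff it ends at a non-A reference base or
    at the read end; it is uncensored iff followed by an unedited reference A.
    Returns (length, censored) per run.
    """
    ref = np.asarray(ref_bases)
    read = np.asarray(read_bases)
    if ref.shape != read.shape:
        raise ValueError("reference and read spans differ in length")
    runs = []
    length = 0
    for i in range(len(ref)):
        if ref[i] == BASE_A and read[i] == BASE_G:
            length += 1
            continue
        if length:
            censored = ref[i] != BASE_A
            runs.append((length, bool(censored)))
            length = 0
    if length:
        runs.append((length, True))  # run reached the read end
    return runs


def run_hazard(runs, conf: float = 0.95) -> pd.DataFrame:
    """Discrete hazard of run length with exact (Clopper–Pearson) CIs.

    hazard(n) = #(n long, uncensored) / (#(n long, uncensored) + #(> n long));
    censored runs of length exactly n appear in neither numerator nor
    denominator.  Undefined hazards (zero denominator) are omitted.
    """
    runs = list(runs)
    if any(l < 1 for l, _ in runs):
        raise ValueError("run lengths must be >= 1")
    max_len = max((l for l, _ in runs), default=0)
    alpha = 1.0 - conf
    rows = []
    for n in range(1, max_len + 1):
        num = sum(1 for l, c in runs if l == n and not c)
        longer = sum(1 for l, _ in runs if l > n)
        denom = num + longer
        if denom == 0:
            continue
        lo = sps.beta.ppf(alpha / 2, num, denom - num + 1) if num > 0 else 0.0
        hi = sps.beta.ppf(1 - alpha / 2, num + 1, denom - num) if num < denom else 1.0
        rows.append(
            {"n": n, "hazard": num / denom, "num": num, "denom": denom,
             "ci_low": float(lo), "ci_high": float(hi)}
        )
    return pd.DataFrame(rows, columns=["n", "hazard", "num", "denom", "ci_low", "ci_high"])


def solution_read_runs(solution, genome: RepeatGenome, min_mq: int = 30):
    """Per-read editing runs from MAP alignments with MQ >= ``min_mq``.

    Each aligned end of each confidently placed read is strand-normalized to
    the edited strand of its copy (reverse-edited copies are complemented and
    reversed) before run extraction; reads in not-edited copies are skipped.
    """
    from .repeat_model import revcomp as _rc

    runs = []
    states = solution.states.states
    for (cand, post, mq), cs in zip(
        solution.map_alignments(), solution.compiled.sets
    ):
        if mq < min_mq:
            continue
        st = int(states[cand.copy])
        if st == NOT_EDITED:
            continue
        for end, seq in ((cand.end1, cs.pair.seq1), (cand.end2, cs.pair.seq2)):
            if end is None or end.positions is not None:
                continue
            ref = genome.seq[end.start : end.start + end.length]
            read = seq if end.strand == 1 else _rc(seq)
            if st == EDITED_REVERSE:
                ref = COMPLEMENT[ref][::-1]
                read = COMPLEMENT[read][::-1]
            runs.extend(extract_runs(ref, read))
    return runs


# --------------------------------------------------------------------------
# Sequence context
# --------------------------------------------------------------------------


def context_fractions(
    ref_bases: np.ndarray,
    positions: np.ndarray,
    levels: np.ndarray,
    frame: str = "centered",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean editing level per three-letter context, with pairwise tests.

    ``ref_bases`` is the strand-normalized reference (edited base = A);
    ``positions``/``levels`` give the editing fraction at each eligible
    adenosine.  ``frame`` is "centered" (5' base, A, 3' base) or
    "three_prime" (the context *ending* at the edited base).  Positions whose
    context would be truncated by a sequence edge are skipped.  Returns the
    per-context summary and the pairwise Welch t-tests with BHY FDR.
    """
    ref = np.asarray(ref_bases)
    groups: dict[str, list[float]] = {}
    for pos, lv in zip(np.asarray(positions), np.asarray(levels)):
        if frame == "centered":
            lo, hi = pos - 1, pos + 2
        elif frame == "three_prime":
            lo, hi = pos - 2, pos + 1
        else:
            raise ValueError(f"unknown frame {frame!r}")
        if lo < 0 or hi > len(ref):
            continue
        ctx = decode_seq(ref[lo:hi])
        groups.setdefault(ctx, []).append(float(lv))
    summary = pd.DataFrame(
        [
            {"context": c, "mean_level": float(np.mean(v)), "count": len(v)}
            for c, v in sorted(groups.items())
        ],
        columns=["context", "mean_level", "count"],
    )
    tests = []
    for a, b in combinations(sorted(groups), 2):
        va, vb = groups[a], groups[b]
        if len(va) < 2 or len(vb) < 2:
            continue
        t, p = sps.ttest_ind(va, vb, equal_var=False)
        tests.append({"context_a": a, "context_b": b, "t": float(t), "p": float(p)})
    tests_df = pd.DataFrame(tests, columns=["context_a", "context_b", "t", "p"])
    if len(tests_df):
        from statsmodels.stats.multitest import multipletests

        tests_df["fdr_bhy"] = multipletests(tests_df["p"], method="fdr_by")[1]
    else:
        tests_df["fdr_bhy"] = pd.Series(dtype=float)
    return summary, tests_df


# --------------------------------------------------------------------------
# Helix segmentation
# --------------------------------------------------------------------------


@dataclass
class Helix:
    pairs: list[tuple[int, int]]

    @property
    def length(self) -> int:
        return len(self.pairs)

    def positions(self) -> set[int]:
        return {p for ij in self.pairs for p in ij}


class StructureParseError(ValueError):
    pass


def parse_dot_bracket(struct: str) -> list[tuple[int, int]]:
    """Base pairs (i, j), i < j, 0-based, from nested dot-bracket notation."""
    stacks: dict[str, list[int]] = {"(": [], "[": [], "{": [], "<": []}
    close = {")": "(", "]": "[", "}": "{", ">": "<"}
    pairs = []
    for i, ch in enumerate(struct):
        if ch in stacks:
            stacks[ch].append(i)
        elif ch in close:
            st = stacks[close[ch]]
            if not st:
                raise StructureParseError(f"unmatched {ch!r} at position {i}")
            pairs.append((st.pop(), i))
        elif ch not in ".-,_:":
            raise StructureParseError(f"unexpected character {ch!r} at position {i}")
    for op, st in stacks.items():
        if st:
            raise StructureParseError(f"unmatched {op!r} at position {st[-1]}")
    return sorted(pairs)


def parse_ct(path) -> tuple[str, list[tuple[int, int]]]:
    """Sequence and base pairs from a CT (connectivity table) file."""
    with open(path) as fh:
        lines = [ln for ln in fh if ln.strip()]
    try:
        n = int(lines[0].split()[0])
    except (IndexError, ValueError) as exc:
        raise StructureParseError("malformed CT header") from exc
    seq = []
    pairs = []
    for ln in lines[1 : n + 1]:
        parts = ln.split()
        idx, base, partner = int(parts[0]), parts[1], int(parts[4])
        seq.append(base)
        if partner > idx:
            pairs.append((idx - 1, partner - 1))
    return "".join(seq), sorted(pairs)


def helix_segments(
    pairs: list[tuple[int, int]] | str, max_bulge: int = 2
) -> list[Helix]:
    """Maximal helices: stacked pairs merged across interior bulges of up to
    ``max_bulge`` unpaired bases on one or both sides.  Helix length is the
    number of base pairs."""
    if isinstance(pairs, str):
        pairs = parse_dot_bracket(pairs)
    pairs = sorted(pairs)
    helices: list[Helix] = []
    cur: list[tuple[int, int]] = []
    for i, j in pairs:
        if cur:
            i0, j0 = cur[-1]
            if i > i0 and j < j0 and (i - i0 - 1) <= max_bulge and (j0 - j - 1) <= max_bulge:
                cur.append((i, j))
                continue
            helices.append(Helix(cur))
        cur = [(i, j)]
    if cur:
        helices.append(Helix(cur))
    return helices


def helix_depth(struct_len: int, pairs: list[tuple[int, int]]) -> np.ndarray:
    """Per position, distance along the sequence to the nearest unpaired
    position (0 at unpaired positions)."""
    paired = np.zeros(struct_len, dtype=bool)
    for i, j in pairs:
        paired[i] = paired[j] = True
    depth = np.zeros(struct_len, dtype=np.int64)
    unpaired_idx = np.flatnonzero(~paired)
    if unpaired_idx.size == 0:
        depth[:] = struct_len  # fully paired: effectively infinite depth
        return depth
    idx = np.arange(struct_len)
    ins = np.searchsorted(unpaired_idx, idx)
    left = np.where(ins > 0, idx - unpaired_idx[np.maximum(ins - 1, 0)], np.iinfo(np.int64).max)
    right = np.where(
        ins < unpaired_idx.size, unpaired_idx[np.minimum(ins, unpaired_idx.size - 1)] - idx,
        np.iinfo(np.int64).max,
    )
    return np.minimum(left, right)


def helix_binned_editing(
    ref_bases: np.ndarray,
    helices: list[Helix],
    edited_levels: dict[int, float],
    bins: list[int] | None = None,
    conf: float = 0.95,
) -> pd.DataFrame:
    """Per helix-length bin: fraction of A positions with any predicted
    editing (binomial CI) and mean editing level (normal-approximation CI).

    ``bins`` are right-open length boundaries, e.g. [0, 18, 32, 64] yields
    [0,18), [18,32), [32,64), [64, inf).  Empty bins are reported with
    count 0.
    """
    if bins is None:
        bins = [0, 18, 32, 64]
    ref = np.asarray(ref_bases)
    alpha = 1.0 - conf
    edges = list(bins) + [np.inf]
    rows = []
    for b in range(len(bins)):
        lo, hi = edges[b], edges[b + 1]
        a_pos = [
            p
            for h in helices
            if lo <= h.length < hi
            for p in sorted(h.positions())
            if ref[p] == BASE_A
        ]
        n = len(a_pos)
        lv = [edited_levels.get(p, 0.0) for p in a_pos]
        k = sum(1 for p in a_pos if p in edited_levels)
        frac = k / n if n else float("nan")
        f_lo = sps.beta.ppf(alpha / 2, k, n - k + 1) if k > 0 else 0.0
        f_hi = sps.beta.ppf(1 - alpha / 2, k + 1, n - k) if 0 <= k < n else 1.0
        mean = float(np.mean(lv)) if n else float("nan")
        sem = float(np.std(lv, ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
        zcrit = sps.norm.ppf(1 - alpha / 2)
        rows.append(
            {
                "bin_low": lo,
                "bin_high": hi,
                "n_adenosines": n,
                "n_edited": k,
                "fraction_edited": frac,
                "fraction_ci_low": float(f_lo) if n else float("nan"),
                "fraction_ci_high": float(f_hi) if n else float("nan"),
                "mean_level": mean,
                "mean_ci_low": mean - zcrit * sem if n > 1 else float("nan"),
                "mean_ci_high": mean + zcrit * sem if n > 1 else float("nan"),
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Clone statistics
# --------------------------------------------------------------------------


def clone_edit_statistics(
    reference: str, clones: list[str]
) -> tuple[int, int, float]:
    """Descriptive statistics of Sanger-cloned sequences aligned to a region.

    Clones are gap-free strings aligned to ``reference`` (same length).
    Returns (#adenosines edited in >= 1 clone, #adenosines, mean edited
    adenosines per clone), where edited means reference A read as G.
    """
    from .repeat_model import encode_seq

    ref = encode_seq(reference)
    a_mask = ref == BASE_A
    n_a = int(a_mask.sum())
    any_edited = np.zeros(len(ref), dtype=bool)
    per_clone = []
    for cl in clones:
        codes = encode_seq(cl)
        if len(codes) != len(ref):
            raise ValueError("clone length does not match reference")
        ed = a_mask & (codes == BASE_G)
        any_edited |= ed
        per_clone.append(int(ed.sum()))
    return int(any_edited.sum()), n_a, float(np.mean(per_clone)) if per_clone else 0.0


# --------------------------------------------------------------------------
# Export
# --------------------------------------------------------------------------


def write_edit_sites_tsv(path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False)


def write_edit_sites_vcf(path, table: pd.DataFrame) -> None:
    """Minimal VCF: ALT is the edited base; INFO carries LEVEL/COVERAGE/TIER."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=LEVEL,Number=1,Type=Float,Description="Editing level">\n')
        fh.write('##INFO=<ID=COVERAGE,Number=1,Type=Float,Description="Expected coverage">\n')
        fh.write('##INFO=<ID=TIER,Number=1,Type=String,Description="Confidence tier">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for row in table.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.source_pos + 1}\t.\t{row.ref_base}\t{row.alt_base}"
                f"\t.\tPASS\tLEVEL={row.level:.4f};COVERAGE={row.coverage:.1f};"
                f"TIER={row.tier}\n"
            )
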