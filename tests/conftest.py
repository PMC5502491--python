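import numpy as np
import pytest
from hypothesis import settings

import repprofile as rp
from repprofile import simulate

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


def make_tiny_instance(seed, n_copies=2, core_len=120, flank_len=60, n_reads=40,
                       read_len=30, edit_prob=0.5):
    """Small simulated instance (genome, candidate sets, truth) for
    oracle-equivalence and property tests."""
    rng = np.random.default_rng(seed)
    ref, bed, layout = simulate.make_hypothetical_family(
        rng, core_len=core_len, flank_len=flank_len,
        n_isolated_per_strand=max(1, (n_copies - 2) // 2), spacer=50,
    )
    genome = rp.build_repeat_genome(ref, bed, simulate.FAMILY_NAME, flank=flank_len)
    states = simulate.truth_states(genome, layout)
    if rng.random() > edit_prob:  # sometimes a fully unedited instance
        states.states[:] = 0
    profile, truth = simulate.simulate_profile(genome, states, rng)
    pairs, placements = simulate.simulate_reads(
        genome, profile, n_reads=n_reads, read_len=read_len,
        insert_range=(2 * read_len, 3 * read_len), seed=rng,
    )
    truth.placements = placements
    enum = rp.CandidateEnumerator(genome)
    sets, _ = enum.enumerate_all(pairs)
    return genome, sets, truth


@pytest.fixture(scope="session")
def priors():
    return rp.PriorConfig()


@pytest.fixture(scope="session")
def small_run(priors):
    """Moderate hypothetical-family run (6k pairs) for structural checks."""
    ds = rp.simulate_hypothetical_dataset(seed=7, n_reads=6000)
    enum = rp.CandidateEnumerator(ds.genome, pairing_penalty=priors.unpaired_penalty)
    sets, _ = enum.enumerate_all(ds.pairs)
    compiled = rp.CompiledCandidates(sets, ds.genome, priors)
    best, maxima = rp.run_with_restarts(compiled, ds.genome, priors, max_steps=40)
    return {"ds": ds, "compiled": compiled, "best": best, "maxima": maxima}


@pytest.fixture(scope="session")
def paper_scale_run(priors):
    """Full hypothetical-family run at the design's 50,000 read pairs.

    Shared by the accuracy, mapping-quality and level-recovery checks.
    """
    ds = rp.simulate_hypothetical_dataset(seed=1, n_reads=50_000)
    enum = rp.CandidateEnumerator(ds.genome, pairing_penalty=priors.unpaired_penalty)
    sets, _ = enum.enumerate_all(ds.pairs)
    compiled = rp.CompiledCandidates(sets, ds.genome, priors)
    best, maxima = rp.run_with_restarts(compiled, ds.genome, priors, max_steps=50)
    tiers = rp.classify_confidence(maxima)
    sites = rp.call_edit_sites(best, ds.genome, tiers=tiers)
    return {
        "ds": ds,
        "compiled": compiled,
        "best": best,
        "maxima": maxima,
        "tiers": tiers,
        "sites": sites,
    }


def duplex_read_accuracy(run):
    """(pct MQ>=30 among duplex-interior reads, pct correctly placed among
    those, n interior reads) for a completed hypothetical-family run."""
    ds, compiled, best = run["ds"], run["compiled"], run["best"]
    read_len = len(ds.pairs[0].seq1)
    dup = set(simulate.duplex_core_positions(ds.genome, ds.layout))
    maps = best.map_alignments()
    id2i = {cs.pair.id: i for i, cs in enumerate(compiled.sets)}
    n_int = n_mq = n_correct = 0
    for row in ds.truth.placements.itertuples(index=False):
        interior = all(
            p in dup for s in (row.start1, row.start2) for p in (s, s + read_len - 1)
        )
        if not interior:
            continue
        i = id2i.get(row.read_id)
        if i is None:
            continue
        cand, post, mq = maps[i]
        n_int += 1
        if mq >= 30:
            n_mq += 1
            n_correct += (
                cand.end1 is not None
                and cand.end2 is not None
                and cand.end1.start == row.start1
                and cand.end1.strand == row.strand1
                and cand.end2.start == row.start2
                and cand.end2.strand == row.strand2
            )
    pct_mq = 100.0 * n_mq / n_int if n_int else float("nan")
    pct_correct = 100.0 * n_correct / n_mq if n_mq else float("nan")
    return pct_mq, pct_correct, n_int
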