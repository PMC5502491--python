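import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import repprofile as rp
from repprofile import postanalysis
from repprofile.repeat_model import encode_seq

U, C = False, True  # censored flags


class TestCallEditSites:
    def test_null_solution_empty_table(self, priors):
        from conftest import make_tiny_instance

        genome, sets, _ = make_tiny_instance(61, edit_prob=0.0, n_reads=60)
        compiled = rp.CompiledCandidates(sets, genome, priors)
        sol = rp.em_run(compiled, genome, priors, max_steps=15)
        table = rp.call_edit_sites(sol, genome)
        assert len(table) == 0

    def test_sites_match_solution_types(self, small_run):
        ds, best = small_run["ds"], small_run["best"]
        table = rp.call_edit_sites(best, ds.genome, min_coverage=1, min_level=0.01)
        typed = np.flatnonzero(best.types.types == rp.TYPE_EDITED)
        assert set(table["position"]).issubset(set(typed))
        # every reported row satisfies the inclusive thresholds
        assert (table["level"] >= 0.01).all()
        assert (table["coverage"] >= 1).all()

    def test_threshold_is_inclusive(self, small_run):
        ds, best = small_run["ds"], small_run["best"]
        full = rp.call_edit_sites(best, ds.genome, min_level=0.0)
        assert len(full) >= len(rp.call_edit_sites(best, ds.genome))
        lv = full["level"].iloc[0]
        at = rp.call_edit_sites(best, ds.genome, min_level=float(lv))
        assert (at["level"] >= lv).all()
        assert int(full["position"].iloc[0]) in set(at["position"])


class TestSensitivityPpv:
    def test_worked_example(self):
        sens, ppv = rp.sensitivity_ppv({1, 2, 3}, {2, 3, 4})
        assert (sens, ppv) == (pytest.approx(2 / 3), pytest.approx(2 / 3))

    def test_perfect_prediction(self):
        assert rp.sensitivity_ppv({5, 6}, {5, 6}) == (1.0, 1.0)

    def test_empty_sets_undefined(self):
        sens, ppv = rp.sensitivity_ppv(set(), set())
        assert np.isnan(sens) and np.isnan(ppv)

    @given(st.sets(st.integers(0, 50)), st.sets(st.integers(0, 50)))
    def test_permutation_invariant(self, pred, true):
        a = rp.sensitivity_ppv(sorted(pred), sorted(true))
        b = rp.sensitivity_ppv(list(pred)[::-1], list(true)[::-1])
        assert a == b or (np.isnan(a[0]) and np.isnan(b[0])) or (
            np.isnan(a[1]) and np.isnan(b[1])
        )


class TestEditingLevelComparison:
    def test_perfect_prediction(self):
        levels = {1: 0.2, 2: 0.9}
        _, slope, rmse = rp.editing_level_comparison(levels, levels)
        assert slope == pytest.approx(1.0)
        assert rmse == pytest.approx(0.0)

    def test_uncovered_site_pairs_with_zero(self):
        pairs, _, _ = rp.editing_level_comparison({}, {7: 0.5})
        assert pairs.loc[0, "true_level"] == 0.5
        assert pairs.loc[0, "predicted_level"] == 0.0

    def test_rmse_matches_hand_computation(self):
        pred = {1: 0.1, 2: 0.5, 3: 0.9, 4: 0.0, 5: 0.3}
        true = {1: 0.2, 2: 0.4, 3: 1.0, 4: 0.1, 5: 0.3}
        _, _, rmse = rp.editing_level_comparison(pred, true)
        hand = np.sqrt(np.mean([0.01, 0.01, 0.01, 0.01, 0.0]))
        assert rmse == pytest.approx(hand)


class TestExtractRuns:
    @pytest.mark.parametrize(
        "ref,read,expected",
        [
            ("AAAA", "GGAA", [(2, U)]),
            ("AAAC", "GGGC", [(3, C)]),
            ("AGAA", "GGGA", [(1, C), (1, U)]),
        ],
    )
    def test_examples(self, ref, read, expected):
        runs = rp.extract_runs(encode_seq(ref), encode_seq(read))
        assert runs == expected

    def test_run_at_read_end_is_censored(self):
        assert rp.extract_runs(encode_seq("CAA"), encode_seq("CGG")) == [(2, C)]

    @given(st.integers(0, 2**31 - 1), st.integers(5, 60))
    def test_lengths_partition_the_span(self, seed, n):
        """Edited-run lengths plus unedited and non-A positions account for
        the whole aligned span."""
        rng = np.random.default_rng(seed)
        ref = rng.integers(0, 4, n)
        read = ref.copy()
        a_pos = np.flatnonzero(ref == 0)
        flips = a_pos[rng.random(len(a_pos)) < 0.5]
        read[flips] = 2
        runs = rp.extract_runs(ref, read)
        assert sum(l for l, _ in runs) == len(flips)
        assert all(l >= 1 for l, _ in runs)


class TestRunHazard:
    def test_single_uncensored_run(self):
        hz = rp.run_hazard([(1, False)])
        assert hz.loc[hz["n"] == 1, "hazard"].item() == 1.0

    def test_worked_example(self):
        hz = rp.run_hazard([(1, False), (1, False), (2, False), (3, True)])
        assert hz.loc[hz["n"] == 1, "hazard"].item() == pytest.approx(0.5)
        assert hz.loc[hz["n"] == 1, "denom"].item() == 4
        assert hz.loc[hz["n"] == 2, "hazard"].item() == pytest.approx(0.5)

    def test_all_censored_undefined_everywhere(self):
        hz = rp.run_hazard([(2, True), (3, True)])
        # hazard defined only where longer runs exist but numerator counts 0
        assert (hz["num"] == 0).all()
        assert 3 not in set(hz["n"])  # length-3 censored excluded entirely

    def test_rejects_zero_length(self):
        with pytest.raises(ValueError):
            rp.run_hazard([(0, False)])

    @given(st.lists(st.integers(1, 10), min_size=1, max_size=100))
    def test_uncensored_equals_empirical_hazard(self, lengths):
        """Fully uncensored data: the estimator equals the direct empirical
        discrete hazard of the length distribution."""
        runs = [(l, False) for l in lengths]
        hz = rp.run_hazard(runs)
        for row in hz.itertuples(index=False):
            at_least = sum(1 for l in lengths if l >= row.n)
            exactly = sum(1 for l in lengths if l == row.n)
            assert row.hazard == pytest.approx(exactly / at_least)

    def test_recovers_increasing_hazard_from_processive_editing(self):
        """Synthetic processive-editing runs drawn from a known increasing
        hazard, censored at random A-tract ends, recover the hazard shape."""
        rng = np.random.default_rng(42)
        true_h = {1: 0.15, 2: 0.25, 3: 0.45, 4: 0.65, 5: 0.85}

        def draw_run():
            n = 1
            while n < 6 and rng.random() > true_h.get(n, 1.0):
                n += 1
            return n

        runs = []
        for _ in range(6000):
            n = draw_run()
            tract = rng.integers(1, 10)  # available adenosines before a non-A
            if n > tract:
                runs.append((int(tract), True))
            else:
                runs.append((int(n), False))
        hz = rp.run_hazard(runs).set_index("n")["hazard"]
        est = [hz.get(n, np.nan) for n in range(1, 6)]
        assert np.all(np.diff(est) > 0)  # increasing
        for n in range(1, 6):
            assert est[n - 1] == pytest.approx(true_h[n], abs=0.06)


class TestContextFractions:
    def test_equal_levels_give_equal_means(self):
        ref = encode_seq("TTAATTAATTAA")
        pos = np.array([2, 6, 10])
        summary, _ = rp.context_fractions(ref, pos, np.full(3, 0.4))
        assert np.allclose(summary["mean_level"], 0.4)

    def test_hand_computed_means(self):
        ref = encode_seq("GTACGTACGAAGGAAG")
        # contexts: positions 2, 6 are TA_, positions 10, 14 are AA_
        pos = np.array([2, 6, 10, 14])
        lv = np.array([0.3, 0.4, 0.0, 0.1])
        summary, _ = rp.context_fractions(ref, pos, lv)
        means = dict(zip(summary["context"], summary["mean_level"]))
        assert means["TAC"] == pytest.approx(0.35)
        assert means["AAG"] == pytest.approx(0.05)

    def test_edge_positions_skipped(self):
        ref = encode_seq("AAAA")
        summary, _ = rp.context_fractions(ref, np.array([0, 3]), np.array([0.5, 0.5]))
        assert summary["count"].sum() == 0 or 0 not in summary.index

    def test_imposed_five_prime_ordering_recovered(self):
        """Simulated levels with imposed 5' preference T > A > C > G are
        recovered in the context means, with significant pairwise FDRs."""
        rng = np.random.default_rng(7)
        mean_by_prev = {"T": 0.35, "A": 0.29, "C": 0.08, "G": 0.03}
        chars = "ACGT"
        seq = []
        positions, levels = [], []
        i = 0
        for _ in range(400):
            prev = chars[rng.integers(0, 4)]
            seq.extend([prev, "A", chars[rng.integers(0, 4)]])
            positions.append(i + 1)
            levels.append(
                float(np.clip(rng.normal(mean_by_prev[prev], 0.05), 0.0, 1.0))
            )
            i += 3
        ref = encode_seq("".join(seq))
        summary, tests = rp.context_fractions(
            ref, np.array(positions), np.array(levels)
        )
        summary["prev"] = summary["context"].str[0]
        by_prev = summary.groupby("prev").apply(
            lambda d: np.average(d["mean_level"], weights=d["count"]),
            include_groups=False,
        )
        assert by_prev["T"] > by_prev["A"] > by_prev["C"] > by_prev["G"]
        assert (tests["fdr_bhy"] <= 1.0).all()

    def test_three_prime_frame(self):
        ref = encode_seq("GGTAGG")
        summary, _ = rp.context_fractions(
            ref, np.array([3]), np.array([0.2]), frame="three_prime"
        )
        assert summary.loc[0, "context"] == "GTA"


class TestHelixSegments:
    def test_simple_stem(self):
        helices = rp.helix_segments("((((....))))")
        assert len(helices) == 1 and helices[0].length == 4

    def test_two_base_bulge_merges(self):
        # two 3-pair stacks with a 2-base bulge on one side
        struct = "(((..(((....))))))"
        helices = rp.helix_segments(struct)
        assert len(helices) == 1 and helices[0].length == 6

    def test_three_base_bulge_splits(self):
        struct = "(((...(((....))))))"
        helices = rp.helix_segments(struct)
        assert sorted(h.length for h in helices) == [3, 3]

    def test_bulges_on_both_sides_merge(self):
        struct = "(((..(((....)))..)))"
        helices = rp.helix_segments(struct)
        assert len(helices) == 1 and helices[0].length == 6

    def test_malformed_structure_raises(self):
        with pytest.raises(postanalysis.StructureParseError):
            rp.parse_dot_bracket("(((..")
        with pytest.raises(postanalysis.StructureParseError):
            rp.parse_dot_bracket("..)..")


class TestHelixBinnedEditing:
    def test_all_positions_edited_fraction_one(self):
        struct = "((((....))))"
        helices = rp.helix_segments(struct)
        ref = encode_seq("AAAA" + "GGGG" + "TTTT")
        a_pos = [p for h in helices for p in h.positions() if ref[p] == 0]
        levels = {p: 0.5 for p in a_pos}
        binned = rp.helix_binned_editing(ref, helices, levels, bins=[0])
        assert binned.loc[0, "fraction_edited"] == 1.0

    def test_hand_built_two_bin_case(self):
        ref = encode_seq("AAAAAAAAAAAAAAAAAAAAAAAAAAAAAA")
        short = postanalysis.Helix([(0, 9), (1, 8), (2, 7)])  # 6 A's, len 3
        long = postanalysis.Helix([(10 + i, 29 - i) for i in range(8)])  # len 8
        levels = {0: 0.5, 9: 0.4, 10: 0.2, 11: 0.2, 12: 0.2,
                  29: 0.2, 28: 0.2, 27: 0.2}
        binned = rp.helix_binned_editing(ref, [short, long], levels, bins=[0, 5])
        # short helix: 2 of 6 A positions edited; long: 6 of 16
        assert binned.loc[0, "fraction_edited"] == pytest.approx(2 / 6)
        assert binned.loc[1, "fraction_edited"] == pytest.approx(6 / 16)

    def test_bin_counts_partition_positions(self):
        struct = "(((..(((....)))..)))..((((....))))"
        helices = rp.helix_segments(struct)
        ref = encode_seq("A" * len(struct))
        binned = rp.helix_binned_editing(ref, helices, {}, bins=[0, 4, 8])
        total_a = sum(
            1 for h in helices for p in h.positions() if ref[p] == 0
        )
        assert binned["n_adenosines"].sum() == total_a


class TestHelixDepth:
    def test_depth_zero_at_unpaired(self):
        pairs = rp.parse_dot_bracket("((....))")
        depth = postanalysis.helix_depth(8, pairs)
        assert depth[2] == 0 and depth[0] >= 1

    def test_interior_depth_grows(self):
        struct = ".(((((((((((((((((((((((((....)))))))))))))))))))))))))."
        pairs = rp.parse_dot_bracket(struct)
        depth = postanalysis.helix_depth(len(struct), pairs)
        assert depth[0] == 0  # unpaired terminus
        assert depth[1] == 1  # first pair, one step from the exterior
        # depth increases into the stem until the interior loop takes over
        assert depth[13] == 13
        assert depth[25] == 1  # adjacent to the loop


class TestCloneStatistics:
    def test_synthetic_clone_set(self):
        """Synthetic clones: editing statistics computed by direct counting."""
        rng = np.random.default_rng(3)
        ref = "".join("ACGT"[b] for b in rng.integers(0, 4, 300))
        a_idx = [i for i, ch in enumerate(ref) if ch == "A"]
        clones = []
        edited_union = set()
        per_clone = []
        for _ in range(10):
            clone = list(ref)
            chosen = [i for i in a_idx if rng.random() < 0.25]
            for i in chosen:
                clone[i] = "G"
            edited_union.update(chosen)
            per_clone.append(len(chosen))
            clones.append("".join(clone))
        n_any, n_a, mean_per = rp.clone_edit_statistics(ref, clones)
        assert n_any == len(edited_union)
        assert n_a == len(a_idx)
        assert mean_per == pytest.approx(np.mean(per_clone))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rp.clone_edit_statistics("AAAA", ["AAA"])


class TestExports:
    def test_tsv_and_vcf_round_trip(self, small_run, tmp_path):
        ds, best = small_run["ds"], small_run["best"]
        table = rp.call_edit_sites(best, ds.genome)
        tsv = tmp_path / "sites.tsv"
        postanalysis.write_edit_sites_tsv(tsv, table)
        back = pd.read_csv(tsv, sep="\t")
        assert len(back) == len(table)
        assert list(back["position"]) == list(table["position"])
        vcf = tmp_path / "sites.vcf"
        postanalysis.write_edit_sites_vcf(vcf, table)
        lines = [l for l in vcf.read_text().splitlines() if not l.startswith("#")]
        assert len(lines) == len(table)
        if lines:
            fields = lines[0].split("\t")
            assert fields[4] in {"G", "C"}
            assert "LEVEL=" in fields[7]
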