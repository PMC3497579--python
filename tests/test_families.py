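"""Family attribution: seed marking, alignment oracle, clustering,
split-join metric, threshold optimisation."""

import itertools
import random

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mirevol import families as fam
from mirevol.io_formats import MatureArm, MirnaLocus
from mirevol.synthetic_data import SimulationConfig, simulate_dataset, \
    stripped_loci

from conftest import make_mirna


def brute_force_align(a_enc: str, b_enc: str,
                      scheme: fam.ScoringScheme) -> float:
    """Exhaustive enumeration of all global alignments (affine gaps)."""
    best = [-np.inf]
    la, lb = len(a_enc), len(b_enc)

    def ps(x, y):
        return scheme.pair_score(x.upper(), x.islower(),
                                 y.upper(), y.islower())

    def rec(i, j, score, last):
        if i == la and j == lb:
            if score > best[0]:
                best[0] = score
            return
        if i < la and j < lb:
            rec(i + 1, j + 1, score + ps(a_enc[i], b_enc[j]), "M")
        if i < la:
            rec(i + 1, j,
                score + (scheme.gap_extend if last == "D"
                         else scheme.gap_open), "D")
        if j < lb:
            rec(i, j + 1,
                score + (scheme.gap_extend if last == "I"
                         else scheme.gap_open), "I")

    rec(0, 0, 0.0, None)
    return best[0]


def random_marked(rng: random.Random, n: int) -> fam.SeedMarkedSequence:
    seq = "".join(rng.choice("ACGUN") for _ in range(n))
    mask = tuple(rng.random() < 0.4 for _ in range(n))
    return fam.SeedMarkedSequence(seq, mask)


class TestMarkSeed:
    def test_seed_is_mature_positions_two_to_eight(self):
        locus = make_mirna(arm_start=5)
        marked = fam.mark_seed(locus)
        seed_positions = {i + 1 for i, m in enumerate(marked.seed_mask) if m}
        assert seed_positions == set(range(6, 13))

    def test_two_arms_mark_two_runs(self):
        seq = "A" * 80
        locus = MirnaLocus("m", "A", "chr1", 1, 80, "+", seq,
                           (MatureArm(3, 24), MatureArm(50, 71)))
        marked = fam.mark_seed(locus)
        pos = sorted(i + 1 for i, m in enumerate(marked.seed_mask) if m)
        assert pos == list(range(4, 11)) + list(range(51, 58))


class TestAlignScore:
    def test_plain_self_alignment(self):
        a = fam.SeedMarkedSequence("ACGU", (False,) * 4)
        assert fam.align_score(a, a) == pytest.approx(20.0)

    def test_seed_doubled_self_alignment(self):
        b = fam.SeedMarkedSequence(
            "ACGUACG", (False, True, True, True, False, False, False))
        assert fam.align_score(b, b) == pytest.approx(50.0)  # 4*5 + 3*10

    def test_empty_sequence_rejected(self):
        a = fam.SeedMarkedSequence("ACGU", (False,) * 4)
        with pytest.raises(ValueError, match="mask length"):
            fam.SeedMarkedSequence("", (False,))
        with pytest.raises(ValueError, match="empty"):
            fam.align_score(a, fam.SeedMarkedSequence("", ()))

    def test_matches_exhaustive_enumeration(self):
        rng = random.Random(1)
        scheme = fam.ScoringScheme()
        for _ in range(40):
            a = random_marked(rng, rng.randint(1, 8))
            b = random_marked(rng, rng.randint(1, 8))
            got = fam.align_score(a, b, scheme)
            want = brute_force_align(a.encoded(), b.encoded(), scheme)
            assert got == pytest.approx(want), (a.encoded(), b.encoded())

    def test_symmetry(self):
        rng = random.Random(2)
        for _ in range(10):
            a = random_marked(rng, rng.randint(2, 12))
            b = random_marked(rng, rng.randint(2, 12))
            assert fam.align_score(a, b) == pytest.approx(
                fam.align_score(b, a))

    def test_self_score_dominates_equal_length(self):
        rng = random.Random(3)
        for _ in range(10):
            n = rng.randint(3, 10)
            a = random_marked(rng, n)
            b = random_marked(rng, n)
            assert fam.align_score(a, a) >= fam.align_score(a, b) - 1e-9

    def test_raising_seed_multiplier_never_decreases_seed_pair_score(self):
        rng = random.Random(4)
        s1 = fam.ScoringScheme(seed_multiplier=1.0)
        s2 = fam.ScoringScheme(seed_multiplier=3.0)
        for _ in range(15):
            n = rng.randint(3, 9)
            seq = "".join(rng.choice("ACGU") for _ in range(n))
            mask = tuple(rng.random() < 0.5 for _ in range(n))
            a = fam.SeedMarkedSequence(seq, mask)
            b = random_marked(rng, rng.randint(3, 9))
            assert fam.align_score(a, b, s2) >= \
                fam.align_score(a, b, s1) - 1e-9


def naive_single_linkage(ids, vals, threshold):
    """O(n^3) agglomeration: repeatedly merge any two groups linked by an
    edge with score >= threshold."""
    groups = [{i} for i in ids]
    idx = {x: k for k, x in enumerate(ids)}
    merged = True
    while merged:
        merged = False
        for gi in range(len(groups)):
            for gj in range(gi + 1, len(groups)):
                if any(vals[idx[a], idx[b]] >= threshold
                       for a in groups[gi] for b in groups[gj]):
                    groups[gi] |= groups[gj]
                    del groups[gj]
                    merged = True
                    break
            if merged:
                break
    return {frozenset(g) for g in groups}


class TestSingleLinkage:
    def _table(self, rng, n):
        vals = rng.integers(0, 50, size=(n, n)).astype(float)
        vals = (vals + vals.T) / 2
        ids = [f"x{i}" for i in range(n)]
        return ids, vals, pd.DataFrame(vals, index=ids, columns=ids)

    def test_threshold_above_max_gives_singletons(self):
        rng = np.random.default_rng(0)
        ids, vals, df = self._table(rng, 6)
        part = fam.single_linkage(df, vals.max() + 1)
        assert part.n_families() == 6

    def test_threshold_below_min_gives_one_family(self):
        rng = np.random.default_rng(1)
        ids, vals, df = self._table(rng, 6)
        part = fam.single_linkage(df, vals.min() - 1)
        assert part.n_families() == 1

    def test_matches_naive_agglomeration(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            n = int(rng.integers(2, 13))
            ids, vals, df = self._table(rng, n)
            t = float(rng.integers(0, 50))
            got = {frozenset(s)
                   for s in fam.single_linkage(df, t).as_sets().values()}
            want = naive_single_linkage(ids, vals, t)
            assert got == want

    def test_monotone_refinement(self):
        rng = np.random.default_rng(3)
        ids, vals, df = self._table(rng, 10)
        low = fam.single_linkage(df, 10.0).as_sets().values()
        high = fam.single_linkage(df, 30.0).as_sets().values()
        for h in high:
            assert any(h <= l for l in low)

    def test_missing_entries_rejected(self):
        df = pd.DataFrame([[1.0, np.nan], [np.nan, 1.0]],
                          index=["a", "b"], columns=["a", "b"])
        with pytest.raises(ValueError, match="missing"):
            fam.single_linkage(df, 0.5)


def split_join_direct(a_sets, b_sets, n):
    """Independent re-implementation of the van Dongen formula."""
    pa = sum(max(len(c & d) for d in b_sets) for c in a_sets)
    pb = sum(max(len(d & c) for c in a_sets) for d in b_sets)
    return (n - pa) + (n - pb)


def random_partition(rng, elements):
    k = int(rng.integers(1, len(elements) + 1))
    labels = rng.integers(0, k, size=len(elements))
    sets = {}
    for e, l in zip(elements, labels):
        sets.setdefault(int(l), set()).add(e)
    return fam.FamilyPartition.from_sets(sets.values())


class TestSplitJoin:
    def test_identity(self):
        a = fam.FamilyPartition.from_sets([{"1", "2"}, {"3"}])
        assert fam.split_join(a, a) == 0

    def test_worked_example(self):
        a = fam.FamilyPartition.from_sets([{"1", "2"}, {"3", "4"}])
        b = fam.FamilyPartition.from_sets([{"1", "2", "3", "4"}])
        assert fam.split_join(a, b) == 2
        assert fam.split_join(b, a) == 2

    def test_matches_direct_formula_on_random_partitions(self):
        rng = np.random.default_rng(5)
        elements = [str(i) for i in range(10)]
        for _ in range(50):
            a = random_partition(rng, elements)
            b = random_partition(rng, elements)
            want = split_join_direct(
                list(a.as_sets().values()), list(b.as_sets().values()),
                len(elements))
            assert fam.split_join(a, b) == want

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.lists(st.integers(0, 4), min_size=2, max_size=10),
           st.lists(st.integers(0, 4), min_size=2, max_size=10),
           st.lists(st.integers(0, 4), min_size=2, max_size=10))
    def test_triangle_inequality(self, la, lb, lc):
        n = min(len(la), len(lb), len(lc))
        elements = [str(i) for i in range(n)]

        def part(labels):
            sets = {}
            for e, l in zip(elements, labels):
                sets.setdefault(l, set()).add(e)
            return fam.FamilyPartition.from_sets(sets.values())

        a, b, c = part(la[:n]), part(lb[:n]), part(lc[:n])
        assert fam.split_join(a, c) <= \
            fam.split_join(a, b) + fam.split_join(b, c)

    def test_universe_mismatch_rejected(self):
        a = fam.FamilyPartition.from_sets([{"1"}])
        b = fam.FamilyPartition.from_sets([{"2"}])
        with pytest.raises(ValueError, match="different element"):
            fam.split_join(a, b)


class TestOptimizeThreshold:
    def test_recovers_reference_made_at_known_threshold(self):
        rng = np.random.default_rng(6)
        n = 12
        vals = rng.integers(0, 40, size=(n, n)).astype(float)
        vals = (vals + vals.T) / 2
        ids = [f"x{i}" for i in range(n)]
        df = pd.DataFrame(vals, index=ids, columns=ids)
        reference = fam.single_linkage(df, 20.0)
        t, part, dist = fam.optimize_threshold(df, reference)
        assert dist == 0
        assert {frozenset(s) for s in part.as_sets().values()} == \
            {frozenset(s) for s in reference.as_sets().values()}

    def test_returned_threshold_is_in_grid(self):
        rng = np.random.default_rng(7)
        vals = rng.random((6, 6)) * 30
        vals = (vals + vals.T) / 2
        ids = list("abcdef")
        df = pd.DataFrame(vals, index=ids, columns=ids)
        ref = fam.single_linkage(df, 15.0)
        grid = [5.0, 15.0, 25.0]
        t, _, _ = fam.optimize_threshold(df, ref, thresholds=grid)
        assert t in grid

    def test_planted_families_recovered_without_seed_mutation(self):
        cfg = SimulationConfig(seed=21, n_species=8, n_families=12,
                               sub_in_seed=0.0, sub_off_seed=0.05)
        gt = simulate_dataset(cfg)
        loci = stripped_loci(gt)
        scores = fam.all_vs_all_scores([fam.mark_seed(l) for l in loci])
        truth_sets = {}
        for lid, f in gt.locus_family.items():
            truth_sets.setdefault(f, set()).add(lid)
        reference = fam.FamilyPartition.from_sets(truth_sets.values())
        _, part, dist = fam.optimize_threshold(scores, reference)
        assert dist == 0

    def test_empty_grid_rejected(self):
        df = pd.DataFrame([[1.0, 2.0], [2.0, 1.0]], index=["a", "b"],
                          columns=["a", "b"])
        ref = fam.single_linkage(df, 1.0)
        with pytest.raises(ValueError, match="empty"):
            fam.optimize_threshold(df, ref, thresholds=[])
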