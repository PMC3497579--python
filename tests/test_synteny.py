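"""Synteny: anchor building, collinear-run detection vs brute force,
chaining idempotence, classification, display alignment."""

import itertools

import numpy as np
import pytest

from mirevol.synteny import (
    Anchor,
    AnchorSequence,
    SyntenyParams,
    align_blocks_for_display,
    build_anchors,
    chain_blocks,
    classify_and_measure,
    detect_blocks,
)
from mirevol.synthetic_data import SimulationConfig, simulate_dataset

from conftest import make_mirna, make_protein


def toy_genome(species, families, spacing=2_000, kind="protein",
               chrom="chr1", start=10_000):
    anchors = []
    pos = start
    for i, f in enumerate(families):
        anchors.append(Anchor(f, f"{f}_{species}_{i}", pos, pos + 999, "+",
                              kind))
        pos += 1000 + spacing
    return AnchorSequence(species, chrom, anchors)


def brute_force_runs(seqs, params):
    """Enumerate all maximal common collinear family runs on toy genomes.

    A run occurs in a genome when its families appear in order (or fully
    reversed) with only non-shared anchors between consecutive members —
    at most ``max_mismatch_anchors`` of them and ``max_gap_length`` bp; a
    run is valid when it occurs in >= min_regions genomes, and maximal
    when no longer valid run contains it as an (either-direction)
    subsequence with the same regions. Two-genome toys only.
    """
    assert len(seqs) == 2
    collapsed = {s.key: s.collapsed() for s in seqs}
    (ka, kb) = sorted(collapsed)
    shared = ({a.family for a in collapsed[ka]}
              & {a.family for a in collapsed[kb]})

    def occurs(run, anchors):
        fams = [a.family for a in anchors]
        for target in (run, run[::-1]):
            positions = [i for i, f in enumerate(fams) if f == target[0]]
            for p0 in positions:
                path = [p0]
                ok = True
                for f in target[1:]:
                    nxt = None
                    for q in range(path[-1] + 1, len(fams)):
                        if fams[q] == f:
                            nxt = q
                            break
                    if nxt is None:
                        ok = False
                        break
                    between = fams[path[-1] + 1 : nxt]
                    if any(x in shared for x in between):
                        ok = False
                        break
                    if len(between) > params.max_mismatch_anchors:
                        ok = False
                        break
                    gap = anchors[nxt].start - anchors[path[-1]].end - 1
                    if gap > params.max_gap_length:
                        ok = False
                        break
                    path.append(nxt)
                if ok:
                    return True
        return False

    base = collapsed[ka]
    fams0 = [a.family for a in base]
    # candidates: ordered subsequences of the first genome that never skip
    # a shared anchor and respect the insertion/gap budgets
    candidates = set()

    def grow(path):
        if len(path) >= params.min_anchors:
            run = tuple(fams0[k] for k in path)
            candidates.add(min(run, run[::-1]))
        last = path[-1]
        for q in range(last + 1, len(fams0)):
            between = fams0[last + 1 : q]
            if any(x in shared for x in between):
                break
            if len(between) > params.max_mismatch_anchors:
                break
            if base[q].start - base[last].end - 1 > params.max_gap_length:
                break
            grow(path + [q])

    for i in range(len(fams0)):
        grow([i])
    valid = set()
    for run in candidates:
        n = sum(occurs(run, anchors) for anchors in collapsed.values())
        if n >= params.min_regions:
            valid.add(run)

    def subseq(short, long):
        def contains(sub, seq):
            it = iter(seq)
            return all(x in it for x in sub)

        return contains(short, long) or contains(short[::-1], long)

    return {r for r in valid
            if not any(r != o and subseq(r, o) for o in valid)}


class TestBuildAnchors:
    def test_combined_and_ordered(self):
        prots = [make_protein(f"p{i}", start=1 + 30_000 * i,
                              end=20_000 + 30_000 * i, family=f"PF{i}")
                 for i in range(3)]
        mirs = [make_mirna("m1", start=25_000, family="F1"),
                make_mirna("m2", start=55_000, family="F2")]
        seqs = build_anchors(mirs, prots)
        assert len(seqs) == 1
        fams = [a.family for a in seqs[0].anchors]
        assert fams == ["PF0", "F1", "PF1", "F2", "PF2"]

    def test_exact_duplicates_removed(self):
        m = make_mirna("m1", start=1000, family="F1")
        m2 = make_mirna("m1b", start=1000, family="F1", length=70)
        seqs = build_anchors([m, m2], [])
        assert len(seqs[0].anchors) == 1

    def test_unlabelled_locus_rejected(self):
        with pytest.raises(ValueError, match="no family label"):
            build_anchors([make_mirna("m1")], [])

    def test_synthetic_order_matches_planted(self):
        cfg = SimulationConfig(seed=51, n_species=3, n_families=10)
        gt = simulate_dataset(cfg)
        seqs = build_anchors(gt.mirna_loci, gt.protein_loci)
        for s in seqs:
            assert [a.family for a in s.anchors] == gt.anchor_order[s.species]


class TestDetectBlocks:
    def test_identical_orders_give_one_full_block(self):
        g1 = toy_genome("s1", ["f1", "f2", "f3", "f4", "f5"])
        g2 = toy_genome("s2", ["f1", "f2", "f3", "f4", "f5"])
        blocks = detect_blocks([g1, g2])
        assert len(blocks) == 1
        assert blocks[0].families == ("f1", "f2", "f3", "f4", "f5")
        assert len(blocks[0].occurrences) == 2

    def test_single_foreign_insertion_preserves_block(self):
        g1 = toy_genome("s1", ["f1", "f2", "f3", "f4"])
        g2 = toy_genome("s2", ["f1", "f2", "x", "f3", "f4"])
        blocks = detect_blocks([g1, g2])
        assert [b.families for b in blocks] == [("f1", "f2", "f3", "f4")]

    def test_reversed_run_detected_with_opposite_orientation(self):
        g1 = toy_genome("s1", ["f1", "f2", "f3", "f4"])
        g2 = toy_genome("s2", ["f4", "f3", "f2", "f1"])
        blocks = detect_blocks([g1, g2])
        assert len(blocks) == 1
        oris = {o.species: o.orientation for o in blocks[0].occurrences}
        assert oris["s1"] != oris["s2"]

    def test_large_gap_splits_block(self):
        g1 = toy_genome("s1", ["f1", "f2"], spacing=20_000)
        g2 = toy_genome("s2", ["f1", "f2"], spacing=2_000)
        assert detect_blocks([g1, g2]) == []

    def test_matches_brute_force_on_toy_genomes(self):
        params = SyntenyParams(max_mismatch_anchors=2)
        cases = [
            (["f1", "f2", "f3", "f4"], ["f1", "f2", "f3", "f4"]),
            (["f1", "f2", "f3", "f4"], ["f1", "x", "f2", "f3", "f4"]),
            (["f1", "f2", "f3", "f4"], ["f4", "f3", "f2", "f1"]),
            (["f1", "f2", "f3", "f4", "f5"], ["f1", "f2", "f4", "f5"]),
            (["f1", "f2", "f3"], ["f3", "f1", "f2"]),
        ]
        for fams1, fams2 in cases:
            g1, g2 = toy_genome("s1", fams1), toy_genome("s2", fams2)
            got = {b.families for b in detect_blocks([g1, g2], params)}
            want = brute_force_runs([g1, g2], params)
            assert got == want, (fams1, fams2)

    def test_matches_brute_force_on_random_segment_rearrangements(self):
        # second genome = first with one contiguous segment reversed and
        # up to two foreign insertions (the rearrangement classes the
        # detector claims to resolve exactly)
        params = SyntenyParams(max_mismatch_anchors=2)
        rng = np.random.default_rng(54)
        for trial in range(20):
            n = int(rng.integers(4, 9))
            fams1 = [f"f{i}" for i in range(n)]
            fams2 = list(fams1)
            a, b = sorted(rng.integers(0, n, size=2))
            fams2[a : b + 1] = fams2[a : b + 1][::-1]
            for k in range(int(rng.integers(0, 3))):
                fams2.insert(int(rng.integers(0, len(fams2) + 1)),
                             f"x{trial}_{k}")
            g1, g2 = toy_genome("s1", fams1), toy_genome("s2", fams2)
            got = {x.families for x in detect_blocks([g1, g2], params)}
            want = brute_force_runs([g1, g2], params)
            assert got == want, (trial, fams1, fams2)

    def test_greedy_runs_are_sound_on_shuffled_genomes(self):
        # with multiple interleaved rearrangements the greedy detector is
        # not exhaustive, but every block it reports must still be a valid
        # common collinear run
        params = SyntenyParams(max_mismatch_anchors=2)
        rng = np.random.default_rng(55)
        for trial in range(15):
            n = int(rng.integers(4, 9))
            fams1 = [f"f{i}" for i in range(n)]
            fams2 = list(rng.permutation(fams1))
            g1, g2 = toy_genome("s1", fams1), toy_genome("s2", fams2)
            got = {x.families for x in detect_blocks([g1, g2], params)}
            valid_supersets = brute_force_runs([g1, g2], params)
            all_valid = set()
            for run in valid_supersets:
                all_valid.add(run)
            for run in got:
                # every reported run occurs in both genomes: it must be a
                # (subsequence of a) brute-force-valid run
                assert any(
                    set(run) <= set(v) for v in all_valid
                ), (trial, run, valid_supersets)

    def test_invariant_under_genome_input_order(self):
        g1 = toy_genome("s1", ["f1", "f2", "f3", "x", "f4"])
        g2 = toy_genome("s2", ["f1", "f2", "f3", "f4"])
        g3 = toy_genome("s3", ["f2", "f3", "f4"])
        a = detect_blocks([g1, g2, g3])
        b = detect_blocks([g3, g1, g2])
        assert [(x.families, x.occurrences) for x in a] == \
            [(x.families, x.occurrences) for x in b]

    def test_planted_blocks_recovered_exactly(self):
        cfg = SimulationConfig(seed=52, n_species=3, n_families=12,
                               gain_root_bias=1.0, loss_prob=0.0,
                               dup_rate=0.0)
        gt = simulate_dataset(cfg)
        seqs = build_anchors(gt.mirna_loci, gt.protein_loci)
        blocks = detect_blocks(seqs)
        got = {b.families for b in blocks}
        want = {min(r, r[::-1]) for r in gt.planted_blocks}
        assert got == want
        assert all(len(b.occurrences) == 3 for b in blocks)


class TestChaining:
    def _blocks(self, runs_by_species):
        """Build toy genomes from one family order, then detect."""
        seqs = [toy_genome(sp, fams) for sp, fams in runs_by_species.items()]
        return detect_blocks(seqs)

    def test_shared_terminal_blocks_merge(self):
        g1 = toy_genome("s1", ["f1", "f2", "f3", "f4"])
        g2 = toy_genome("s2", ["f1", "f2", "f3", "f4"])
        blocks = detect_blocks([g1, g2])
        b = blocks[0]
        left = type(b)("blockA", ("f1", "f2", "f3"),
                       tuple(type(o)(o.species, o.chromosome, 10_000,
                                     get_end(g1, "f3"), "+")
                             for o in b.occurrences))
        right = type(b)("blockB", ("f3", "f4"),
                        tuple(type(o)(o.species, o.chromosome,
                                      get_start(g1, "f3"), o.end, "+")
                              for o in b.occurrences))
        chained = chain_blocks([left, right])
        assert len(chained) == 1
        assert chained[0].families in (("f1", "f2", "f3", "f4"),
                                       ("f4", "f3", "f2", "f1"))

    def test_non_overlapping_blocks_not_merged(self):
        g1 = toy_genome("s1", ["f1", "f2", "f3", "f4", "f3"])
        b1 = detect_blocks([g1, toy_genome("s2", ["f1", "f2"])])
        b2 = detect_blocks([toy_genome("s1", ["f4", "f3"], start=200_000),
                            toy_genome("s2", ["f4", "f3"], start=200_000)])
        merged = chain_blocks(b1 + b2)
        assert len(merged) == len(b1 + b2)

    def test_chaining_is_idempotent(self):
        cfg = SimulationConfig(seed=53, n_species=3, n_families=10,
                               n_inversions=1)
        gt = simulate_dataset(cfg)
        seqs = build_anchors(gt.mirna_loci, gt.protein_loci)
        once = chain_blocks(detect_blocks(seqs))
        twice = chain_blocks(once)
        assert [(b.families, b.occurrences) for b in once] == \
            [(b.families, b.occurrences) for b in twice]


def get_start(genome, family):
    return next(a.start for a in genome.anchors if a.family == family)


def get_end(genome, family):
    return next(a.end for a in genome.anchors if a.family == family)


class TestClassifyMeasure:
    def _measure(self, blocks, kinds, sizes):
        return classify_and_measure(blocks, kinds, sizes)

    def test_classes_from_member_kinds(self):
        g1 = toy_genome("s1", ["f1", "f2"], kind="mirna")
        g2 = toy_genome("s2", ["f1", "f2"], kind="mirna")
        blocks = detect_blocks([g1, g2])
        m = self._measure(blocks, {"f1": "mirna", "f2": "mirna"},
                          {"s1": 1_000_000, "s2": 2_000_000})
        assert set(m["class"]) == {"mirna_only"}
        m2 = self._measure(blocks, {"f1": "mirna", "f2": "protein"},
                           {"s1": 1_000_000, "s2": 2_000_000})
        assert set(m2["class"]) == {"mixed"}

    def test_normalized_lengths_in_unit_interval(self):
        g1 = toy_genome("s1", ["f1", "f2", "f3"])
        g2 = toy_genome("s2", ["f1", "f2", "f3"])
        m = self._measure(detect_blocks([g1, g2]),
                          {f: "protein" for f in ("f1", "f2", "f3")},
                          {"s1": 500_000, "s2": 5_000_000})
        assert ((m["normalized_length"] > 0)
                & (m["normalized_length"] <= 1)).all()

    def test_normalization_equalizes_scaled_genomes(self):
        # same block structure, spacer scaled 4x: raw lengths differ,
        # normalised lengths coincide
        g_fish = toy_genome("fish", ["f1", "f2", "f3"], spacing=2_000)
        g_fish2 = toy_genome("fish2", ["f1", "f2", "f3"], spacing=2_000)
        # spacer chosen so spans scale exactly with genome size
        g_mam = toy_genome("mam", ["f1", "f2", "f3"], spacing=9_000)
        g_mam2 = toy_genome("mam2", ["f1", "f2", "f3"], spacing=9_000)
        kinds = {f: "protein" for f in ("f1", "f2", "f3")}
        m1 = self._measure(detect_blocks([g_fish, g_fish2]), kinds,
                           {"fish": 100_000, "fish2": 100_000})
        m2 = self._measure(detect_blocks([g_mam, g_mam2]), kinds,
                           {"mam": 300_000, "mam2": 300_000})
        assert m1["length_bp"].iloc[0] != m2["length_bp"].iloc[0]
        assert m1["normalized_length"].iloc[0] == pytest.approx(
            m2["normalized_length"].iloc[0], rel=1e-9)

    def test_zero_genome_size_rejected(self):
        g1 = toy_genome("s1", ["f1", "f2"])
        g2 = toy_genome("s2", ["f1", "f2"])
        with pytest.raises(ValueError, match="genome size"):
            self._measure(detect_blocks([g1, g2]),
                          {"f1": "protein", "f2": "protein"},
                          {"s1": 0, "s2": 100})


class TestDisplayAlignment:
    def test_identical_occurrences_align_without_gaps(self, tmp_path):
        g1 = toy_genome("s1", ["f1", "f2", "f3"])
        g2 = toy_genome("s2", ["f1", "f2", "f3"])
        blocks = detect_blocks([g1, g2])
        lists = {g.key: g.anchors for g in (g1, g2)}
        svg = tmp_path / "block.svg"
        labels, aligned = align_blocks_for_display(blocks[0], lists,
                                                   svg_path=svg)
        assert svg.exists()
        assert labels == sorted(labels)
        assert all(None not in row for row in aligned)

    def test_extra_family_creates_gap_column(self):
        g1 = toy_genome("s1", ["f1", "f2", "f3"])
        g2 = toy_genome("s2", ["f1", "f2", "x", "f3"])
        blocks = detect_blocks([g1, g2])
        lists = {g.key: g.anchors for g in (g1, g2)}
        _, aligned = align_blocks_for_display(blocks[0], lists)
        assert sum(1 for c in aligned[0] if c is None) == 1
        assert all(c is not None for c in aligned[1])

    def test_single_occurrence_rejected(self):
        g1 = toy_genome("s1", ["f1", "f2"])
        g2 = toy_genome("s2", ["f1", "f2"])
        b = detect_blocks([g1, g2])[0]
        single = type(b)(b.block_id, b.families, b.occurrences[:1])
        with pytest.raises(ValueError, match=">= 2"):
            align_blocks_for_display(single, {g1.key: g1.anchors})
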