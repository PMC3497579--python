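"""miRNA family attribution.

Precursor stem-loops are compared by global (end-to-end) alignment under a
scoring scheme that doubles the reward for matches inside the seed region
(mature positions 2-8), implemented as an expanded nucleotide alphabet in
which seed residues are distinct codes. Families are the connected
components of the score graph at a threshold (single-linkage), and the
threshold is chosen to minimise the split-join partition distance to a
reference family assignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .io_formats import MirnaLocus

__all__ = [
    "ScoringScheme",
    "SeedMarkedSequence",
    "FamilyPartition",
    "mark_seed",
    "align_score",
    "all_vs_all_scores",
    "single_linkage",
    "split_join",
    "optimize_threshold",
]


@dataclass(frozen=True)
class ScoringScheme:
    """Alignment scoring; seed matches score ``match * seed_multiplier``.

    The multiplier applies only when BOTH aligned positions are seed-marked
    (``seed_mode="both"``); set ``seed_mode="either"`` to reward matches
    where at least one side is in seed. Gap cost for a run of length k is
    ``gap_open + (k - 1) * gap_extend``; end gaps are penalised (global-
    global alignment).
    """

    match: float = 5.0
    mismatch: float = -4.0
    gap_open: float = -10.0
    gap_extend: float = -2.0
    seed_multiplier: float = 2.0
    seed_mode: str = "both"

    def __post_init__(self):
        if not (self.match > 0 > self.mismatch):
            raise ValueError("need match > 0 > mismatch")
        if not (self.gap_open <= self.gap_extend <= 0):
            raise ValueError("need gap_open <= gap_extend <= 0")
        if self.seed_multiplier < 1:
            raise ValueError("seed multiplier must be >= 1")
        if self.seed_mode not in ("both", "either"):
            raise ValueError("seed_mode must be 'both' or 'either'")

    def pair_score(self, base_a: str, seed_a: bool, base_b: str,
                   seed_b: bool) -> float:
        """Score of aligning two residues (the substitution function)."""
        if base_a != base_b or base_a == "N" or base_b == "N":
            return self.mismatch
        if self.seed_mode == "both":
            in_seed = seed_a and seed_b
        else:
            in_seed = seed_a or seed_b
        return self.match * self.seed_multiplier if in_seed else self.match


@dataclass(frozen=True)
class SeedMarkedSequence:
    """A precursor over the expanded alphabet base x {seed, non-seed}."""

    sequence: str
    seed_mask: tuple[bool, ...]
    locus_id: str = ""

    def __post_init__(self):
        if len(self.sequence) != len(self.seed_mask):
            raise ValueError("mask length != sequence length")

    def __len__(self) -> int:
        return len(self.sequence)

    def encoded(self) -> str:
        """Seed positions as lowercase codes (the expanded alphabet)."""
        return "".join(
            c.lower() if m else c
            for c, m in zip(self.sequence, self.seed_mask)
        )


def mark_seed(locus: MirnaLocus) -> SeedMarkedSequence:
    """Mark the seed region(s): precursor offsets (arm start+1)..(arm start+7).

    These are mature positions 2-8. With two annotated arms the union of
    both seed runs is marked.
    """
    mask = [False] * len(locus.precursor)
    for arm in locus.mature_arms:
        if arm.length < 8:
            raise ValueError(
                f"{locus.locus_id}: arm too short for a seed (len {arm.length})"
            )
        for off in range(arm.start + 1, arm.start + 8):  # 1-based offsets 2-8
            mask[off - 1] = True
    return SeedMarkedSequence(locus.precursor, tuple(mask), locus.locus_id)


_ALPHABET = "ACGUNacgun"


def _build_aligner(scheme: ScoringScheme) -> Align.PairwiseAligner:
    mat = substitution_matrices.Array(alphabet=_ALPHABET, dims=2)
    for a in _ALPHABET:
        for b in _ALPHABET:
            mat[a, b] = scheme.pair_score(
                a.upper(), a.islower(), b.upper(), b.islower()
            )
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = mat
    aligner.open_gap_score = scheme.gap_open
    aligner.extend_gap_score = scheme.gap_extend
    return aligner


_aligner_cache: dict[ScoringScheme, Align.PairwiseAligner] = {}


def align_score(a: SeedMarkedSequence, b: SeedMarkedSequence,
                scheme: ScoringScheme = ScoringScheme()) -> float:
    """Optimal global-alignment score of two seed-marked precursors."""
    if len(a) == 0 or len(b) == 0:
        raise ValueError("cannot align an empty sequence")
    aligner = _aligner_cache.get(scheme)
    if aligner is None:
        aligner = _aligner_cache[scheme] = _build_aligner(scheme)
    return float(aligner.score(a.encoded(), b.encoded()))


def all_vs_all_scores(
    marked: Sequence[SeedMarkedSequence],
    scheme: ScoringScheme = ScoringScheme(),
    max_loci: int = 5000,
) -> pd.DataFrame:
    """Symmetric pairwise score table over all loci (O(n^2) alignments)."""
    if len(marked) > max_loci:
        raise ValueError(
            f"{len(marked)} loci exceed max_loci={max_loci}; raise the guard "
            "explicitly if this is intended"
        )
    ids = [m.locus_id for m in marked]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate locus ids")
    aligner = _aligner_cache.get(scheme)
    if aligner is None:
        aligner = _aligner_cache[scheme] = _build_aligner(scheme)
    enc = [m.encoded() for m in marked]
    n = len(marked)
    out = np.zeros((n, n))
    for i in range(n):
        out[i, i] = aligner.score(enc[i], enc[i])
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = aligner.score(enc[i], enc[j])
    return pd.DataFrame(out, index=ids, columns=ids)


# ---------------------------------------------------------------------------
# Partitions
# ---------------------------------------------------------------------------


@dataclass
class FamilyPartition:
    """A partition of loci into families (single-linkage clustering result)."""

    assignment: dict[str, str]
    threshold: float | None = None
    linkage: str = "single"

    def as_sets(self) -> dict[str, frozenset[str]]:
        out: dict[str, set[str]] = {}
        for lid, fam in self.assignment.items():
            out.setdefault(fam, set()).add(lid)
        return {f: frozenset(s) for f, s in out.items()}

    @classmethod
    def from_sets(cls, sets: Iterable[Iterable[str]],
                  threshold: float | None = None) -> "FamilyPartition":
        assignment = {}
        for group in sets:
            members = sorted(group)
            fam = f"fam_{members[0]}"
            for m in members:
                if m in assignment:
                    raise ValueError(f"locus {m} in two families")
                assignment[m] = fam
        return cls(assignment, threshold)

    @property
    def universe(self) -> frozenset[str]:
        return frozenset(self.assignment)

    def n_families(self) -> int:
        return len(set(self.assignment.values()))


class _DSU:
    def __init__(self, items: Iterable[str]):
        self.parent = {x: x for x in items}

    def find(self, x: str) -> str:
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a: str, b: str) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        if rb < ra:  # deterministic: smaller id wins
            ra, rb = rb, ra
        self.parent[rb] = ra
        return True

    def groups(self) -> list[list[str]]:
        out: dict[str, list[str]] = {}
        for x in self.parent:
            out.setdefault(self.find(x), []).append(x)
        return list(out.values())


def _check_score_table(scores: pd.DataFrame) -> None:
    if list(scores.index) != list(scores.columns):
        raise ValueError("score table rows and columns must list the same loci")
    if scores.isna().any().any():
        raise ValueError("score table has missing pair entries")


def single_linkage(scores: pd.DataFrame, threshold: float) -> FamilyPartition:
    """Families = connected components of the >=threshold score graph.

    Family ids are ``fam_<lexicographically smallest member>``.
    """
    _check_score_table(scores)
    ids = list(scores.index)
    dsu = _DSU(ids)
    vals = scores.to_numpy()
    n = len(ids)
    for i in range(n):
        for j in range(i + 1, n):
            if vals[i, j] >= threshold:
                dsu.union(ids[i], ids[j])
    return FamilyPartition.from_sets(dsu.groups(), threshold=threshold)


def split_join(a: FamilyPartition, b: FamilyPartition) -> int:
    """van Dongen split-join distance between two partitions.

    d(A,B) = (n - sum_C max_D |C ∩ D|) + (n - sum_D max_C |D ∩ C|):
    the number of elements not covered by each side's best-matching
    clusters, summed over both directions. Zero iff identical.
    """
    if a.universe != b.universe:
        raise ValueError("partitions are over different element sets")
    n = len(a.universe)
    sets_a = list(a.as_sets().values())
    sets_b = list(b.as_sets().values())

    def covered(from_sets, to_sets):
        total = 0
        for c in from_sets:
            best = 0
            for d in to_sets:
                inter = len(c & d)
                if inter > best:
                    best = inter
            total += best
        return total

    return (n - covered(sets_a, sets_b)) + (n - covered(sets_b, sets_a))


def optimize_threshold(
    scores: pd.DataFrame,
    reference: FamilyPartition,
    thresholds: Sequence[float] | None = None,
) -> tuple[float, FamilyPartition, int]:
    """Pick the clustering threshold minimising split-join to a reference.

    Candidates default to all distinct observed pairwise scores. Ties are
    broken toward the largest threshold (the most granular partition).
    The sweep is incremental: thresholds are visited in decreasing order
    with a union-find, and the distance is re-evaluated only when a merge
    actually changed the partition.
    """
    _check_score_table(scores)
    ids = list(scores.index)
    if set(ids) != set(reference.universe):
        raise ValueError("reference partition is over different loci")
    vals = scores.to_numpy()
    n = len(ids)
    iu, ju = np.triu_indices(n, k=1)
    edge_scores = vals[iu, ju]
    if thresholds is None:
        cand = np.unique(edge_scores)[::-1]
    else:
        if len(thresholds) == 0:
            raise ValueError("empty threshold grid")
        cand = np.array(sorted(set(thresholds), reverse=True), dtype=float)
    order = np.argsort(edge_scores)[::-1]
    dsu = _DSU(ids)
    ref_sets = reference.as_sets()

    def current_distance() -> int:
        part = FamilyPartition.from_sets(dsu.groups())
        return split_join(part, reference)

    best_t, best_d = None, None
    e = 0
    dirty = True
    last_d = None
    for t in cand:
        while e < len(order) and edge_scores[order[e]] >= t:
            k = order[e]
            if dsu.union(ids[iu[k]], ids[ju[k]]):
                dirty = True
            e += 1
        if dirty or last_d is None:
            last_d = current_distance()
            dirty = False
        if best_d is None or last_d < best_d:
            best_d, best_t = last_d, float(t)
    part = single_linkage(scores, best_t)
    return best_t, part, best_d
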