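"""Collinear synteny blocks over family-labelled anchors.

Genomes are reduced to ordered anchor sequences (protein and miRNA loci
identified by family). A greedy left-to-right detector finds maximal runs
of anchor families that appear in the same order (or fully reversed) in
at least ``min_regions`` genome regions, tolerating up to
``max_mismatch_anchors`` non-shared anchors and at most ``max_gap_length``
bp between consecutive shared anchors. Blocks sharing a terminal anchor
are chained when adjacent in every genome; blocks are classified
protein-only / mixed / miRNA-only and their lengths normalised by genome
size for cross-species comparison.

This is a deliberate simplification of graph-based detectors: it honours
the same parameter semantics (gap length, minimum regions/anchors, path
dissimilarity as allowed insertions) without reconstructing a genome
graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .families import FamilyPartition
from .io_formats import MirnaLocus, ProteinLocus

__all__ = [
    "Anchor",
    "AnchorSequence",
    "SyntenyBlock",
    "SyntenyParams",
    "build_anchors",
    "detect_blocks",
    "chain_blocks",
    "classify_and_measure",
    "align_blocks_for_display",
]


@dataclass(frozen=True)
class Anchor:
    family: str
    locus_id: str
    start: int
    end: int
    strand: str
    kind: str  # protein | mirna


@dataclass
class AnchorSequence:
    """Ordered anchors of one species-chromosome."""

    species: str
    chromosome: str
    anchors: list[Anchor]

    @property
    def key(self) -> tuple[str, str]:
        return (self.species, self.chromosome)

    def collapsed(self) -> list[Anchor]:
        """Adjacent same-family anchors collapsed to their first instance
        (tandem duplicates count once for run detection)."""
        out: list[Anchor] = []
        for a in self.anchors:
            if out and out[-1].family == a.family:
                continue
            out.append(a)
        return out


@dataclass(frozen=True)
class BlockOccurrence:
    species: str
    chromosome: str
    start: int
    end: int
    orientation: str  # + canonical order, - reversed

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class SyntenyBlock:
    block_id: str
    families: tuple[str, ...]
    occurrences: tuple[BlockOccurrence, ...]
    block_class: str = ""

    @property
    def n_anchors(self) -> int:
        return len(self.families)


@dataclass(frozen=True)
class SyntenyParams:
    max_gap_length: int = 10_000
    min_regions: int = 2
    min_anchors: int = 2
    max_mismatch_anchors: int = 10


def build_anchors(
    mirna_loci: list[MirnaLocus],
    protein_loci: list[ProteinLocus],
    partition: FamilyPartition | None = None,
) -> list[AnchorSequence]:
    """Combine the datasets into per-chromosome ordered anchor lists.

    miRNA family labels come from ``partition`` when given, else from the
    locus itself; an unlabelled locus is an error. Exact duplicates (same
    family at the same position) are dropped.
    """
    records: dict[tuple[str, str], list[Anchor]] = {}
    for locus in mirna_loci:
        fam = locus.family_id
        if partition is not None:
            fam = partition.assignment.get(locus.locus_id, fam)
        if not fam:
            raise ValueError(f"{locus.locus_id}: no family label")
        records.setdefault((locus.species, locus.chromosome), []).append(
            Anchor(fam, locus.locus_id, locus.start, locus.end,
                   locus.strand, "mirna")
        )
    for p in protein_loci:
        records.setdefault((p.species, p.chromosome), []).append(
            Anchor(p.family_id, p.locus_id, p.start, p.end, p.strand,
                   "protein")
        )
    out = []
    for (sp, chrom), anchors in sorted(records.items()):
        anchors.sort(key=lambda a: (a.start, a.end, a.family, a.locus_id))
        dedup: list[Anchor] = []
        seen = set()
        for a in anchors:
            sig = (a.family, a.start, a.end)
            if sig in seen:
                continue
            seen.add(sig)
            dedup.append(a)
        out.append(AnchorSequence(sp, chrom, dedup))
    return out


# ---------------------------------------------------------------------------
# Detection
# ---------------------------------------------------------------------------


def _pairwise_runs(
    A: list[Anchor], B: list[Anchor], params: SyntenyParams, direction: int
) -> list[tuple[list[int], list[int]]]:
    """Greedy collinear runs between two collapsed anchor lists.

    Returns (indices into A, indices into B) pairs; B is traversed in
    ``direction`` (+1 forward, -1 reversed). Seeds are taken left to right
    in A; anchors already in a run are not re-seeded.
    """
    pos_b: dict[str, list[int]] = {}
    for j, a in enumerate(B):
        pos_b.setdefault(a.family, []).append(j)
    shared = {a.family for a in A} & set(pos_b)
    runs = []
    for i, anchor in enumerate(A):
        if anchor.family not in pos_b:
            continue
        for j0 in pos_b[anchor.family]:
            ia, ib = [i], [j0]
            while True:
                nxt = _next_match(A, B, ia[-1], ib[-1], pos_b, shared,
                                  params, direction)
                if nxt is None:
                    break
                ia.append(nxt[0])
                ib.append(nxt[1])
            if len(ia) >= params.min_anchors:
                runs.append((ia, ib))
    return runs


def _next_match(A, B, ai, bj, pos_b, shared, params, direction):
    """Next extension (ai', bj') within the insertion and gap budgets.

    Only non-shared anchors may sit between consecutive run members (in
    either genome); the first shared anchor encountered in A is the forced
    candidate, so skipping shared content ends the run."""
    skipped = 0
    for ai2 in range(ai + 1, len(A)):
        if A[ai2].start - A[ai].end - 1 > params.max_gap_length:
            return None
        fam = A[ai2].family
        if fam not in shared:
            skipped += 1
            if skipped > params.max_mismatch_anchors:
                return None
            continue
        # nearest occurrence in B beyond bj in the travel direction
        candidates = [
            j for j in pos_b[fam]
            if (j > bj if direction > 0 else j < bj)
        ]
        if not candidates:
            return None
        bj2 = min(candidates) if direction > 0 else max(candidates)
        lo, hi = (bj, bj2) if direction > 0 else (bj2, bj)
        between = [B[k].family for k in range(lo + 1, hi)]
        if any(f in shared for f in between):
            return None
        if len(between) > params.max_mismatch_anchors:
            return None
        if B[hi].start - B[lo].end - 1 > params.max_gap_length:
            return None
        return ai2, bj2
    return None


def _occurrence(seq: AnchorSequence, collapsed: list[Anchor],
                idx: list[int], orientation: str) -> BlockOccurrence:
    starts = [collapsed[i].start for i in idx]
    ends = [collapsed[i].end for i in idx]
    return BlockOccurrence(seq.species, seq.chromosome, min(starts),
                           max(ends), orientation)


def detect_blocks(
    sequences: list[AnchorSequence],
    params: SyntenyParams = SyntenyParams(),
) -> list[SyntenyBlock]:
    """Detect collinear blocks across >= 2 genomes.

    Runs are found pairwise (every pair of regions, both orientations),
    keyed by their canonical family tuple (lexicographic minimum of the
    run and its reverse) and merged; a block is kept when its occurrence
    set spans at least ``min_regions`` regions. Deterministic: regions are
    processed in sorted order and ties resolve left-to-right.
    """
    if len(sequences) < 2:
        raise ValueError("need at least 2 genomes")
    seqs = sorted(sequences, key=lambda s: s.key)
    collapsed = {s.key: s.collapsed() for s in seqs}
    found: dict[tuple[str, ...], dict] = {}
    for x in range(len(seqs)):
        for y in range(x + 1, len(seqs)):
            sa, sb = seqs[x], seqs[y]
            A, B = collapsed[sa.key], collapsed[sb.key]
            for direction in (+1, -1):
                for ia, ib in _pairwise_runs(A, B, params, direction):
                    run = tuple(A[i].family for i in ia)
                    canon = min(run, run[::-1])
                    flip = run != canon
                    occ_a = _occurrence(sa, A, ia,
                                        "-" if flip else "+")
                    ori_b_same = direction > 0
                    ori_b = occ_a.orientation if ori_b_same else (
                        "-" if occ_a.orientation == "+" else "+")
                    occ_b = _occurrence(sb, B, ib, ori_b)
                    entry = found.setdefault(canon, {"occ": set()})
                    entry["occ"].add(occ_a)
                    entry["occ"].add(occ_b)
    # drop runs contained in a longer found run (order-preserving
    # subsequence, either direction) covering the same regions — pairwise
    # detection produces every suffix and skip variant of a kept run
    blocks = []
    keys = sorted(found, key=lambda k: (-len(k), k))
    kept: list[tuple[tuple[str, ...], set]] = []
    for run in keys:
        occ = found[run]["occ"]
        regions = {(o.species, o.chromosome) for o in occ}
        if len(occ) < params.min_regions:
            continue
        redundant = False
        for other_run, other_regions in kept:
            if regions <= other_regions and _is_subsequence(run, other_run):
                redundant = True
                break
        if redundant:
            continue
        kept.append((run, regions))
        blocks.append(
            SyntenyBlock(
                block_id="",
                families=run,
                occurrences=tuple(
                    sorted(occ, key=lambda o: (o.species, o.chromosome,
                                               o.start))
                ),
            )
        )
    blocks.sort(key=lambda b: (b.occurrences[0].species,
                               b.occurrences[0].start, b.families))
    for k, b in enumerate(blocks, 1):
        b.block_id = f"block{k:04d}"
    return blocks


def _is_subsequence(short: tuple, long: tuple) -> bool:
    if len(short) > len(long):
        return False

    def contains(sub, seq):
        it = iter(seq)
        return all(x in it for x in sub)

    return contains(short, long) or contains(short[::-1], long)


# ---------------------------------------------------------------------------
# Chaining
# ---------------------------------------------------------------------------


def _try_merge(x: SyntenyBlock, y: SyntenyBlock) -> SyntenyBlock | None:
    """Merge two blocks sharing a terminal anchor, if adjacent everywhere."""
    gx = {(o.species, o.chromosome) for o in x.occurrences}
    gy = {(o.species, o.chromosome) for o in y.occurrences}
    if gx != gy:
        return None
    fx, fy = x.families, y.families
    merged: tuple[str, ...] | None = None
    for a in (fx, fx[::-1]):
        for b in (fy, fy[::-1]):
            if a[-1] == b[0]:
                merged = a + b[1:]
                break
        if merged:
            break
    if merged is None:
        return None
    occ_x = {(o.species, o.chromosome): o for o in x.occurrences}
    occ_y = {(o.species, o.chromosome): o for o in y.occurrences}
    new_occ = []
    for key in occ_x:
        ox, oy = occ_x[key], occ_y[key]
        # adjacency: the shared terminal anchor sits in both spans, so the
        # spans must physically overlap in this genome
        if not (ox.start <= oy.end and oy.start <= ox.end):
            return None
        new_occ.append(
            BlockOccurrence(ox.species, ox.chromosome,
                            min(ox.start, oy.start), max(ox.end, oy.end),
                            ox.orientation)
        )
    canon = min(merged, merged[::-1])
    return SyntenyBlock(
        block_id=min(x.block_id, y.block_id),
        families=canon,
        occurrences=tuple(sorted(new_occ, key=lambda o: (o.species,
                                                         o.chromosome,
                                                         o.start))),
    )


def chain_blocks(blocks: list[SyntenyBlock]) -> list[SyntenyBlock]:
    """Chain blocks sharing a terminal anchor family.

    A merge requires the same genome set, a shared terminal family in a
    compatible orientation, and physically overlapping occurrence spans in
    every genome (the shared anchor sits in both). Idempotent: chaining a
    chained result changes nothing.
    """
    blocks = list(blocks)
    changed = True
    while changed:
        changed = False
        for i in range(len(blocks)):
            for j in range(i + 1, len(blocks)):
                merged = _try_merge(blocks[i], blocks[j])
                if merged is not None:
                    blocks = (
                        blocks[:i] + [merged] + blocks[i + 1 : j]
                        + blocks[j + 1 :]
                    )
                    changed = True
                    break
            if changed:
                break
    return blocks


# ---------------------------------------------------------------------------
# Classification and measurement
# ---------------------------------------------------------------------------


def classify_and_measure(
    blocks: list[SyntenyBlock],
    family_kinds: dict[str, str],
    genome_sizes: dict[str, int],
) -> pd.DataFrame:
    """Classify blocks and tabulate occurrence lengths per species.

    ``family_kinds`` maps family id -> protein|mirna. Returns one row per
    block occurrence with raw and genome-size-normalised lengths; blocks
    are classed protein_only / mixed / mirna_only from their member kinds.
    """
    rows = []
    for b in blocks:
        kinds = {family_kinds[f] for f in b.families}
        if kinds == {"protein"}:
            b.block_class = "protein_only"
        elif kinds == {"mirna"}:
            b.block_class = "mirna_only"
        else:
            b.block_class = "mixed"
        for o in b.occurrences:
            size = genome_sizes[o.species]
            if size <= 0:
                raise ValueError(f"{o.species}: genome size must be > 0")
            rows.append(
                {
                    "block_id": b.block_id,
                    "class": b.block_class,
                    "species": o.species,
                    "chromosome": o.chromosome,
                    "start": o.start,
                    "end": o.end,
                    "orientation": o.orientation,
                    "length_bp": o.length,
                    "normalized_length": o.length / size,
                    "n_anchors": b.n_anchors,
                }
            )
    return pd.DataFrame(rows)


def cumulative_length_table(measures: pd.DataFrame,
                            normalized: bool = True) -> pd.DataFrame:
    """Per class and species: sorted lengths with cumulative fractions."""
    col = "normalized_length" if normalized else "length_bp"
    out = []
    for (cls, sp), grp in measures.groupby(["class", "species"]):
        lengths = np.sort(grp[col].to_numpy())
        for k, val in enumerate(lengths, 1):
            out.append({"class": cls, "species": sp, col: val,
                        "cumulative_fraction": k / len(lengths)})
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Display alignment
# ---------------------------------------------------------------------------


def _nw_symbols(a: list[str], b: list[str], match: float = 1.0,
                mismatch: float = -1.0, gap: float = -1.0):
    """Global alignment of two symbol lists; returns aligned lists with
    None as the gap symbol."""
    n, m = len(a), len(b)
    score = np.zeros((n + 1, m + 1))
    score[:, 0] = np.arange(n + 1) * gap
    score[0, :] = np.arange(m + 1) * gap
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            sub = match if a[i - 1] == b[j - 1] else mismatch
            score[i, j] = max(score[i - 1, j - 1] + sub,
                              score[i - 1, j] + gap,
                              score[i, j - 1] + gap)
    out_a, out_b = [], []
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0 and score[i, j] == score[i - 1, j - 1] + (
                match if a[i - 1] == b[j - 1] else mismatch):
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i, j = i - 1, j - 1
        elif i > 0 and score[i, j] == score[i - 1, j] + gap:
            out_a.append(a[i - 1])
            out_b.append(None)
            i -= 1
        else:
            out_a.append(None)
            out_b.append(b[j - 1])
            j -= 1
    return out_a[::-1], out_b[::-1]


def align_blocks_for_display(
    block: SyntenyBlock,
    anchor_lists: dict[tuple[str, str], list[Anchor]],
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -1.0,
    svg_path=None,
    intronic_loci: set[str] | None = None,
) -> tuple[list[str], list[list[Anchor | None]]]:
    """Progressively align a block's occurrences by anchor family.

    Occurrences (rows) are sorted alphabetically by species. Each row's
    anchors are those inside the occurrence span, oriented to the block's
    canonical direction; rows are aligned with a symbol-level global
    aligner (same family = match). Returns (row labels, aligned anchor
    rows with None for gaps); optionally renders an SVG where proteins are
    marked "P" and intronic miRNA anchors "I".
    """
    if len(block.occurrences) < 2:
        raise ValueError("display alignment needs >= 2 occurrences")
    occs = sorted(block.occurrences, key=lambda o: (o.species, o.chromosome,
                                                    o.start))
    rows: list[list[Anchor]] = []
    labels: list[str] = []
    for o in occs:
        anchors = [a for a in anchor_lists[(o.species, o.chromosome)]
                   if a.start >= o.start and a.end <= o.end]
        if o.orientation == "-":
            anchors = anchors[::-1]
        rows.append(anchors)
        labels.append(f"{o.species}:{o.chromosome}:{o.start}-{o.end}")
    aligned: list[list[Anchor | None]] = [rows[0]]
    for row in rows[1:]:
        ref = [None if col is None else col.family
               for col in _merge_columns(aligned)]
        new_a, new_b = _nw_symbols(ref, [a.family for a in row],
                                   match, mismatch, gap)
        aligned = _expand(aligned, new_a)
        merged_row: list[Anchor | None] = []
        it = iter(row)
        for sym in new_b:
            merged_row.append(next(it) if sym is not None else None)
        aligned.append(merged_row)
    if svg_path is not None:
        _render_block_svg(labels, aligned, svg_path,
                          intronic_loci or set())
    return labels, aligned


def _merge_columns(aligned: list[list[Anchor | None]]) -> list[Anchor | None]:
    """Column representative: the first non-gap anchor in each column."""
    out = []
    for col in zip(*aligned):
        rep = next((a for a in col if a is not None), None)
        out.append(rep)
    return out


def _expand(aligned: list[list[Anchor | None]],
            new_ref: list) -> list[list[Anchor | None]]:
    """Re-space existing rows to the gapped reference."""
    out = [[] for _ in aligned]
    col = 0
    for sym in new_ref:
        if sym is None:
            for r in out:
                r.append(None)
        else:
            for r, row in zip(out, aligned):
                r.append(row[col])
            col += 1
    return out


def _render_block_svg(labels, aligned, svg_path, intronic_loci) -> None:
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from matplotlib.patches import Rectangle

    families = sorted({a.family for row in aligned for a in row if a})
    cmap = plt.get_cmap("tab20")
    colors = {f: cmap(i % 20) for i, f in enumerate(families)}
    with plt.rc_context({"svg.hashsalt": "mirevol"}):
        ncol = len(aligned[0]) if aligned else 0
        fig, ax = plt.subplots(
            figsize=(0.45 * ncol + 2.5, 0.5 * len(aligned) + 1))
        for r, row in enumerate(aligned):
            for c, anchor in enumerate(row):
                if anchor is None:
                    continue
                ax.add_patch(Rectangle((c, len(aligned) - 1 - r), 0.9, 0.8,
                                       facecolor=colors[anchor.family],
                                       edgecolor="black", lw=0.3))
                mark = ""
                if anchor.kind == "protein":
                    mark = "P"
                elif anchor.locus_id in intronic_loci:
                    mark = "I"
                if mark:
                    ax.text(c + 0.45, len(aligned) - 1 - r + 0.4, mark,
                            ha="center", va="center", fontsize=7)
        ax.set_yticks(np.arange(len(aligned)) + 0.4, labels[::-1], fontsize=7)
        ax.set_xlim(0, max(ncol, 1))
        ax.set_ylim(0, len(aligned))
        ax.set_xticks([])
        fig.tight_layout()
        fig.savefig(svg_path, format="svg", metadata={"Date": None})
        plt.close(fig)
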