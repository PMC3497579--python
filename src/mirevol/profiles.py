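"""Profile matrices and genomic-context annotation.

Builds family x species presence and copy-number matrices from labelled
loci, classifies each miRNA locus as intronic (strictly inside a protein
gene and overlapping no exon) or intergenic, chains loci into genomic
clusters by a gap threshold (default 10 kb), and renders the copy-number
glyph grid (white 0, rainbow 1-9, black >= 10).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .families import FamilyPartition
from .io_formats import MirnaLocus, ProfileMatrix, ProteinLocus, SpeciesTree

__all__ = [
    "ContextAnnotation",
    "build_matrices",
    "annotate_context",
    "assign_clusters",
    "family_context_flags",
    "render_family_glyph",
    "GLYPH_BINS",
]


@dataclass
class ContextAnnotation:
    """Per-locus context: intronic/intergenic, host gene, cluster id."""

    context: dict[str, str] = field(default_factory=dict)
    host: dict[str, str] = field(default_factory=dict)
    cluster: dict[str, str] = field(default_factory=dict)
    cluster_threshold: int = 10_000

    def merge(self, other: "ContextAnnotation") -> "ContextAnnotation":
        out = ContextAnnotation(cluster_threshold=self.cluster_threshold)
        out.context = {**self.context, **other.context}
        out.host = {**self.host, **other.host}
        out.cluster = {**self.cluster, **other.cluster}
        return out

    def is_clustered(self, locus_id: str) -> bool:
        return bool(self.cluster.get(locus_id, ""))

    def to_frame(self) -> pd.DataFrame:
        ids = sorted(set(self.context) | set(self.cluster))
        return pd.DataFrame(
            {
                "locus_id": ids,
                "context": [self.context.get(i, "") for i in ids],
                "host": [self.host.get(i, "") for i in ids],
                "cluster_id": [self.cluster.get(i, "") for i in ids],
            }
        ).set_index("locus_id")


def build_matrices(
    loci: list[MirnaLocus],
    partition: FamilyPartition,
    tree: SpeciesTree,
) -> tuple[ProfileMatrix, ProfileMatrix]:
    """Count loci per (family, species) and derive presence from counts."""
    leaf_set = set(tree.leaf_labels)
    for locus in loci:
        if locus.species not in leaf_set:
            raise ValueError(f"{locus.locus_id}: species {locus.species!r} "
                             "is not a tree leaf")
        if locus.locus_id not in partition.assignment:
            raise ValueError(f"{locus.locus_id}: no family assignment")
    families = sorted(set(partition.assignment.values()))
    counts = pd.DataFrame(0, index=families, columns=sorted(leaf_set),
                          dtype=int)
    for locus in loci:
        fam = partition.assignment[locus.locus_id]
        counts.loc[fam, locus.species] += 1
    count_m = ProfileMatrix(counts, mode="count")
    return count_m.to_presence(), count_m


def annotate_context(
    mirna_loci: list[MirnaLocus],
    protein_loci: list[ProteinLocus],
    require_same_strand: bool = False,
) -> ContextAnnotation:
    """Classify each miRNA locus as intronic or intergenic.

    Intronic means fully contained in a protein locus span and overlapping
    none of its exons; any exon overlap (even 1 bp) disqualifies. When a
    locus sits inside several nested hosts the shortest one wins.
    """
    ann = ContextAnnotation()
    by_chrom: dict[tuple[str, str], list[ProteinLocus]] = {}
    for p in protein_loci:
        by_chrom.setdefault((p.species, p.chromosome), []).append(p)
    for locus in mirna_loci:
        candidates = []
        for p in by_chrom.get((locus.species, locus.chromosome), []):
            if require_same_strand and p.strand != locus.strand:
                continue
            if p.start <= locus.start and locus.end <= p.end:
                exon_hit = any(
                    not (locus.end < s or locus.start > e)
                    for s, e in p.exons
                )
                if not exon_hit:
                    candidates.append(p)
        if candidates:
            host = min(candidates, key=lambda p: (p.length, p.locus_id))
            ann.context[locus.locus_id] = "intronic"
            ann.host[locus.locus_id] = host.locus_id
        else:
            ann.context[locus.locus_id] = "intergenic"
    return ann


def assign_clusters(
    mirna_loci: list[MirnaLocus],
    threshold: int = 10_000,
) -> ContextAnnotation:
    """Chain loci into clusters along each species-chromosome.

    Consecutive loci (sorted by start; strand ignored) sharing a gap
    ``next.start - prev.end - 1 <= threshold`` join one cluster. Clusters
    of size 1 are solo: their cluster id is the empty string. Cluster ids
    are ``<species>_<chrom>_cl<k>`` numbered along the chromosome, so the
    result does not depend on input order.
    """
    ann = ContextAnnotation(cluster_threshold=threshold)
    groups: dict[tuple[str, str], list[MirnaLocus]] = {}
    for locus in mirna_loci:
        groups.setdefault((locus.species, locus.chromosome), []).append(locus)
    for (sp, chrom), loci in sorted(groups.items()):
        loci = sorted(loci, key=lambda l: (l.start, l.end, l.locus_id))
        chains: list[list[MirnaLocus]] = []
        for locus in loci:
            if chains and locus.start - chains[-1][-1].end - 1 <= threshold:
                chains[-1].append(locus)
            else:
                chains.append([locus])
        for k, chain in enumerate(chains, 1):
            cid = f"{sp}_{chrom}_cl{k}" if len(chain) > 1 else ""
            for locus in chain:
                ann.cluster[locus.locus_id] = cid
    return ann


def family_context_flags(
    loci: list[MirnaLocus],
    partition: FamilyPartition,
    annotation: ContextAnnotation,
) -> tuple[dict[str, bool], dict[str, bool]]:
    """Flag each family intronic / clustered by majority of its loci.

    A family counts as intronic (resp. clustered) when more than half of
    its present-day loci are intronic (resp. members of a cluster).
    """
    per_family: dict[str, list[MirnaLocus]] = {}
    for locus in loci:
        fam = partition.assignment[locus.locus_id]
        per_family.setdefault(fam, []).append(locus)
    intronic, clustered = {}, {}
    for fam, members in per_family.items():
        n = len(members)
        n_int = sum(
            annotation.context.get(l.locus_id, "") == "intronic"
            for l in members
        )
        n_clu = sum(annotation.is_clustered(l.locus_id) for l in members)
        intronic[fam] = n_int * 2 > n
        clustered[fam] = n_clu * 2 > n
    return intronic, clustered


# glyph colour bins: copy number -> colour. 0 is white, 1-9 a rainbow
# gradient red->violet, >=10 black.
GLYPH_BINS: list[tuple[int, str]] = [
    (0, "#ffffff"),
    (1, "#ff0000"),
    (2, "#ff7f00"),
    (3, "#ffd400"),
    (4, "#7fff00"),
    (5, "#00cc44"),
    (6, "#00ccff"),
    (7, "#0044ff"),
    (8, "#7f00ff"),
    (9, "#9400d3"),
    (10, "#000000"),
]


def glyph_color(count: int) -> str:
    """Colour for a copy number: white 0, rainbow 1-9, black >= 10."""
    if count < 0:
        raise ValueError("negative copy number")
    return GLYPH_BINS[min(count, 10)][1]


def render_family_glyph(
    counts: ProfileMatrix,
    families: list[str] | None = None,
    species_order: list[str] | None = None,
    svg_path=None,
) -> pd.DataFrame:
    """Render the copy-number glyph grid; return the legend/bin table.

    Each cell is coloured by :func:`glyph_color`. The returned table maps
    every (family, species) cell to its count and colour so the figure's
    content is machine-checkable.
    """
    data = counts.data
    if families is not None:
        data = data.loc[families]
    if species_order is not None:
        data = data[species_order]
    records = []
    for fam in data.index:
        for sp in data.columns:
            c = int(data.loc[fam, sp])
            records.append(
                {"family": fam, "species": sp, "count": c,
                 "color": glyph_color(c)}
            )
    legend = pd.DataFrame(records)
    if svg_path is not None:
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt
        from matplotlib.patches import Rectangle

        with plt.rc_context({"svg.hashsalt": "mirevol"}):
            nf, ns = len(data.index), len(data.columns)
            fig, ax = plt.subplots(
                figsize=(0.25 * ns + 2, 0.25 * nf + 1)
            )
            for i, fam in enumerate(data.index):
                for j, sp in enumerate(data.columns):
                    ax.add_patch(
                        Rectangle((j, nf - 1 - i), 1, 1,
                                  facecolor=glyph_color(int(data.loc[fam, sp])),
                                  edgecolor="grey", lw=0.3)
                    )
            ax.set_xlim(0, ns)
            ax.set_ylim(0, nf)
            ax.set_xticks(np.arange(ns) + 0.5, data.columns, rotation=90,
                          fontsize=6)
            ax.set_yticks(np.arange(nf) + 0.5, list(data.index)[::-1],
                          fontsize=6)
            fig.tight_layout()
            fig.savefig(svg_path, format="svg", metadata={"Date": None})
            plt.close(fig)
    return legend
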