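"""Domain types and file formats shared by every pipeline stage.

Internal coordinate convention is 1-based inclusive (GFF3/Ensembl style);
BED input is converted on read. Mature-arm offsets are always given in
precursor 5'->3' orientation regardless of genomic strand, matching miRBase
annotation practice. All text readers accept plain or gzip-compressed files.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "SpeciesTree",
    "MirnaLocus",
    "ProteinLocus",
    "ProfileMatrix",
    "read_newick",
    "write_newick",
    "read_fasta",
    "write_fasta",
    "read_loci",
    "read_profile_matrix",
    "write_profile_matrix",
    "open_text",
]

RNA_ALPHABET = frozenset("ACGUN")


def open_text(source, mode: str = "rt"):
    """Open a path (gzip-aware by suffix) or pass a stream through."""
    if hasattr(source, "read") or hasattr(source, "write"):
        return source
    path = Path(source)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# Species tree
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TreeNode:
    """A node of a rooted binary tree; ``length`` is the branch to the parent."""

    id: int
    label: str | None
    length: float
    parent: int | None
    children: tuple[int, ...]

    @property
    def is_leaf(self) -> bool:
        return not self.children


class SpeciesTree:
    """Rooted, binary branching phylogram: the frame for ancestral inference.

    Nodes are integer-indexed; leaves carry unique species labels and every
    branch has a non-negative length in substitutions/site. The root carries
    length 0.
    """

    def __init__(self, nodes: Sequence[TreeNode], root: int):
        self.nodes: tuple[TreeNode, ...] = tuple(nodes)
        self.root = root
        self._validate()
        self._leaf_index = {
            n.label: n.id for n in self.nodes if n.is_leaf
        }

    def _validate(self) -> None:
        labels = [n.label for n in self.nodes if n.is_leaf]
        if len(set(labels)) != len(labels):
            dup = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate leaf labels: {dup}")
        if any(l is None or l == "" for l in labels):
            raise ValueError("every leaf must carry a species label")
        for n in self.nodes:
            if n.length < 0:
                raise ValueError(f"negative branch length at node {n.id}")
            if n.children and len(n.children) != 2:
                name = n.label or f"node {n.id}"
                raise ValueError(
                    f"non-binary node {name!r}: {len(n.children)} children"
                )
        if self.nodes[self.root].parent is not None:
            raise ValueError("root must have no parent")

    # -- basic queries ------------------------------------------------------

    def __len__(self) -> int:
        return len(self.nodes)

    @property
    def leaves(self) -> list[TreeNode]:
        return [n for n in self.nodes if n.is_leaf]

    @property
    def leaf_labels(self) -> list[str]:
        return sorted(self._leaf_index)

    def leaf_id(self, label: str) -> int:
        return self._leaf_index[label]

    def postorder(self) -> Iterator[TreeNode]:
        stack = [(self.root, False)]
        while stack:
            nid, done = stack.pop()
            if done:
                yield self.nodes[nid]
            else:
                stack.append((nid, True))
                for c in self.nodes[nid].children:
                    stack.append((c, False))

    def preorder(self) -> Iterator[TreeNode]:
        stack = [self.root]
        while stack:
            nid = stack.pop()
            yield self.nodes[nid]
            stack.extend(reversed(self.nodes[nid].children))

    def leaves_under(self, node_id: int) -> list[int]:
        out, stack = [], [node_id]
        while stack:
            nid = stack.pop()
            n = self.nodes[nid]
            if n.is_leaf:
                out.append(nid)
            else:
                stack.extend(n.children)
        return out

    def leaf_labels_under(self, node_id: int) -> set[str]:
        return {self.nodes[i].label for i in self.leaves_under(node_id)}

    def path_to_root(self, node_id: int) -> list[int]:
        path = [node_id]
        while self.nodes[path[-1]].parent is not None:
            path.append(self.nodes[path[-1]].parent)
        return path

    def node_age(self, node_id: int) -> float:
        """Branch-length distance from the root (proxy for node age)."""
        return sum(self.nodes[i].length for i in self.path_to_root(node_id)[:-1])

    def mrca(self, labels: Iterable[str]) -> int:
        ids = [self.leaf_id(l) for l in labels]
        if not ids:
            raise ValueError("mrca of an empty label set")
        paths = [set(self.path_to_root(i)) for i in ids]
        common = set.intersection(*paths)
        # deepest common ancestor = the one whose path to root is shortest
        return max(common, key=lambda nid: len(self.path_to_root(nid)))

    # -- construction helpers ----------------------------------------------

    @classmethod
    def from_arrays(
        cls,
        parents: Sequence[int | None],
        lengths: Sequence[float],
        labels: Sequence[str | None],
    ) -> "SpeciesTree":
        children: dict[int, list[int]] = {i: [] for i in range(len(parents))}
        root = None
        for i, p in enumerate(parents):
            if p is None:
                root = i
            else:
                children[p].append(i)
        if root is None:
            raise ValueError("no root (node with parent None)")
        nodes = [
            TreeNode(i, labels[i], float(lengths[i]), parents[i], tuple(children[i]))
            for i in range(len(parents))
        ]
        return cls(nodes, root)

    def newick(self) -> str:
        def render(nid: int) -> str:
            n = self.nodes[nid]
            if n.is_leaf:
                body = n.label
            else:
                body = "(" + ",".join(render(c) for c in n.children) + ")"
                if n.label:
                    body += n.label
            if nid == self.root:
                return body
            return f"{body}:{n.length:.12g}"

        return render(self.root) + ";"


def read_newick(source) -> SpeciesTree:
    """Parse a rooted binary Newick tree with branch lengths.

    Polytomies are a hard error (the node is named in the message), as are
    malformed inputs (the parser reports the failure position).
    """
    stream = open_text(source)
    text = stream.read()
    try:
        dt = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:  # dendropy raises schema-specific errors
        raise ValueError(f"Newick parse error: {exc}") from exc
    # map dendropy nodes to contiguous ids, preorder
    dnodes = list(dt.preorder_node_iter())
    index = {id(d): i for i, d in enumerate(dnodes)}
    parents, lengths, labels = [], [], []
    for d in dnodes:
        parents.append(index[id(d.parent_node)] if d.parent_node else None)
        lengths.append(float(d.edge.length) if d.edge.length is not None else 0.0)
        if d.taxon is not None:
            labels.append(d.taxon.label)
        else:
            labels.append(d.label)
    for d, lab in zip(dnodes, labels):
        nchild = len(d.child_nodes())
        if nchild not in (0, 2):
            name = lab or f"node {index[id(d)]}"
            raise ValueError(f"non-binary node {name!r}: {nchild} children")
    return SpeciesTree.from_arrays(parents, lengths, labels)


def write_newick(tree: SpeciesTree, target) -> None:
    stream = open_text(target, "wt")
    stream.write(tree.newick() + "\n")


# ---------------------------------------------------------------------------
# Loci
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MatureArm:
    """Offsets of a mature miRNA within its precursor, 1-based inclusive."""

    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class MirnaLocus:
    """A miRNA precursor locus with mature-arm annotation.

    Coordinates are 1-based inclusive. ``context`` and ``cluster_id`` are
    filled by the profiles stage; ``family_id`` by the families stage.
    """

    locus_id: str
    species: str
    chromosome: str
    start: int
    end: int
    strand: str
    precursor: str
    mature_arms: tuple[MatureArm, ...]
    family_id: str = ""
    context: str = ""
    cluster_id: str = ""

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"{self.locus_id}: start > end")
        if self.strand not in "+-":
            raise ValueError(f"{self.locus_id}: strand must be + or -")
        if set(self.precursor) - RNA_ALPHABET:
            bad = sorted(set(self.precursor) - RNA_ALPHABET)
            raise ValueError(f"{self.locus_id}: non-RNA characters {bad}")
        plen = len(self.precursor)
        if self.end - self.start + 1 != plen:
            raise ValueError(
                f"{self.locus_id}: span {self.end - self.start + 1} != "
                f"precursor length {plen}"
            )
        if not 1 <= len(self.mature_arms) <= 2:
            raise ValueError(f"{self.locus_id}: need 1-2 mature arms")
        for arm in self.mature_arms:
            if arm.start < 1 or arm.end > plen:
                raise ValueError(
                    f"{self.locus_id}: mature arm [{arm.start},{arm.end}] "
                    f"outside precursor [1,{plen}]"
                )
            if arm.length < 8:
                raise ValueError(
                    f"{self.locus_id}: mature arm length {arm.length} < 8 "
                    "(seed positions 2-8 must exist)"
                )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def with_family(self, family_id: str) -> "MirnaLocus":
        return replace(self, family_id=family_id)


@dataclass(frozen=True)
class ProteinLocus:
    """A protein-coding locus with exon structure and a mandatory family id."""

    locus_id: str
    species: str
    chromosome: str
    start: int
    end: int
    strand: str
    family_id: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self):
        if not self.family_id:
            raise ValueError(f"{self.locus_id}: protein family id is mandatory")
        if self.start > self.end:
            raise ValueError(f"{self.locus_id}: start > end")
        prev_end = None
        for s, e in self.exons:
            if s > e or s < self.start or e > self.end:
                raise ValueError(
                    f"{self.locus_id}: exon [{s},{e}] outside locus span"
                )
            if prev_end is not None and s <= prev_end:
                raise ValueError(f"{self.locus_id}: exons overlap or unsorted")
            prev_end = e

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def introns(self) -> list[tuple[int, int]]:
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 > e1 + 1:
                out.append((e1 + 1, s2 - 1))
        return out


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(source) -> dict[str, str]:
    """Read FASTA into an id->sequence dict (id = first word of header)."""
    stream = open_text(source)
    seqs: dict[str, str] = {}
    name, chunks = None, []
    for line in stream:
        line = line.rstrip("\n")
        if line.startswith(">"):
            if name is not None:
                seqs[name] = "".join(chunks)
            name = line[1:].split()[0]
            if name in seqs:
                raise ValueError(f"duplicate FASTA id {name!r}")
            chunks = []
        elif line:
            chunks.append(line.upper())
    if name is not None:
        seqs[name] = "".join(chunks)
    return seqs


def write_fasta(seqs: dict[str, str], target, width: int = 70) -> None:
    stream = open_text(target, "wt")
    for name in seqs:
        stream.write(f">{name}\n")
        s = seqs[name]
        for i in range(0, len(s), width):
            stream.write(s[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Loci readers (GFF3 / BED + mature-arm table)
# ---------------------------------------------------------------------------


def _parse_gff_attributes(text: str) -> dict[str, str]:
    out = {}
    for part in text.strip().split(";"):
        if part and "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_loci(
    annotation_source,
    fasta_source=None,
    fmt: str = "gff3",
    chromosome_lengths: dict[str, int] | None = None,
) -> tuple[list[MirnaLocus], list[ProteinLocus], list[str]]:
    """Read miRNA and protein loci from a GFF3 or BED-like stream.

    GFF3 coordinates are taken as 1-based inclusive, BED as 0-based half-open
    and converted. miRNA records (``type == mirna``) need a precursor sequence
    in ``fasta_source`` keyed by locus id, and carry mature arms in the
    attribute ``mature=start-end[,start-end]`` (precursor offsets, 1-based).
    Protein records (``type == protein``) carry ``family=`` and
    ``exons=s1-e1,s2-e2,...`` in genomic coordinates.

    Returns (mirna_loci, protein_loci, rejection_messages); loci failing an
    invariant are rejected with a reason rather than raising.
    """
    if fmt not in ("gff3", "bed"):
        raise ValueError(f"unknown format {fmt!r}")
    seqs = read_fasta(fasta_source) if fasta_source is not None else {}
    mirnas: list[MirnaLocus] = []
    proteins: list[ProteinLocus] = []
    rejected: list[str] = []
    stream = open_text(annotation_source)
    for lineno, line in enumerate(stream, 1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        if fmt == "gff3":
            if len(f) < 9:
                rejected.append(f"line {lineno}: fewer than 9 GFF3 columns")
                continue
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = f[:9]
            start, end = int(start), int(end)
            attr = _parse_gff_attributes(attrs)
            locus_id = attr.get("ID", f"locus{lineno}")
        else:  # BED: chrom start end name score strand [attrs]
            if len(f) < 6:
                rejected.append(f"line {lineno}: fewer than 6 BED columns")
                continue
            chrom, start, end, locus_id, _score, strand = f[:6]
            start, end = int(start) + 1, int(end)  # to 1-based inclusive
            attr = _parse_gff_attributes(f[6]) if len(f) > 6 else {}
            ftype = attr.get("type", "mirna")
        if chromosome_lengths is not None and chrom in chromosome_lengths:
            if end > chromosome_lengths[chrom] or start < 1:
                rejected.append(
                    f"{locus_id}: coordinates outside chromosome {chrom}"
                )
                continue
        species = attr.get("species", attr.get("genome", ""))
        ftype = (attr.get("type") or ftype).lower()
        try:
            if ftype in ("mirna", "mirna_primary_transcript", "pre_mirna"):
                if locus_id not in seqs:
                    raise ValueError(f"{locus_id}: missing precursor sequence")
                arms = []
                for spanstr in attr.get("mature", "").split(","):
                    if spanstr:
                        a, b = spanstr.split("-")
                        arms.append(MatureArm(int(a), int(b)))
                mirnas.append(
                    MirnaLocus(
                        locus_id=locus_id,
                        species=species,
                        chromosome=chrom,
                        start=start,
                        end=end,
                        strand=strand,
                        precursor=seqs[locus_id].replace("T", "U"),
                        mature_arms=tuple(arms),
                        family_id=attr.get("family", ""),
                    )
                )
            elif ftype in ("protein", "gene", "protein_coding"):
                exons = []
                for spanstr in attr.get("exons", "").split(","):
                    if spanstr:
                        a, b = spanstr.split("-")
                        exons.append((int(a), int(b)))
                proteins.append(
                    ProteinLocus(
                        locus_id=locus_id,
                        species=species,
                        chromosome=chrom,
                        start=start,
                        end=end,
                        strand=strand,
                        family_id=attr.get("family", ""),
                        exons=tuple(exons),
                    )
                )
            else:
                rejected.append(f"{locus_id}: unknown feature type {ftype!r}")
        except ValueError as exc:
            rejected.append(str(exc))
    return mirnas, proteins, rejected


# ---------------------------------------------------------------------------
# Profile matrices
# ---------------------------------------------------------------------------


@dataclass
class ProfileMatrix:
    """Families x species matrix of presence (0/1) or copy number.

    Rows and columns are kept in lexicographic order; ``mode`` is either
    ``"presence"`` or ``"count"``.
    """

    data: pd.DataFrame
    mode: str = "presence"

    def __post_init__(self):
        if self.mode not in ("presence", "count"):
            raise ValueError(f"mode must be presence|count, got {self.mode!r}")
        if self.data.index.has_duplicates:
            raise ValueError("duplicate family ids")
        if self.data.columns.has_duplicates:
            raise ValueError("duplicate species ids")
        self.data = self.data.sort_index(axis=0).sort_index(axis=1)
        vals = self.data.to_numpy()
        if (vals < 0).any():
            raise ValueError("negative values")
        if self.mode == "presence" and not np.isin(vals, (0, 1)).all():
            raise ValueError("presence matrix must be 0/1")
        self.data = self.data.astype(int)

    @property
    def families(self) -> list[str]:
        return list(self.data.index)

    @property
    def species(self) -> list[str]:
        return list(self.data.columns)

    def to_presence(self) -> "ProfileMatrix":
        if self.mode == "presence":
            return self
        return ProfileMatrix((self.data > 0).astype(int), mode="presence")

    def row(self, family: str) -> pd.Series:
        return self.data.loc[family]

    def check_against_tree(self, tree: SpeciesTree) -> None:
        if set(self.species) != set(tree.leaf_labels):
            missing = set(tree.leaf_labels) - set(self.species)
            extra = set(self.species) - set(tree.leaf_labels)
            raise ValueError(
                f"species/tree mismatch: missing {sorted(missing)}, "
                f"extra {sorted(extra)}"
            )


def write_profile_matrix(matrix: ProfileMatrix, target) -> None:
    stream = open_text(target, "wt")
    stream.write(f"#mode={matrix.mode}\n")
    matrix.data.to_csv(stream, sep="\t", index_label="family")


def read_profile_matrix(source) -> ProfileMatrix:
    stream = open_text(source)
    first = stream.readline()
    mode = "presence"
    if first.startswith("#mode="):
        mode = first.strip().split("=", 1)[1]
        body = stream
    else:
        body = io.StringIO(first + stream.read())
    df = pd.read_csv(body, sep="\t", index_col="family")
    df.index.name = None
    df.columns = [str(c) for c in df.columns]
    return ProfileMatrix(df, mode=mode)
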