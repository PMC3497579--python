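"""Shared fixtures: small trees, locus builders, random-tree factory."""

from __future__ import annotations

import io
import random

import numpy as np
import pytest

from mirevol.io_formats import (
    MatureArm,
    MirnaLocus,
    ProteinLocus,
    SpeciesTree,
    read_newick,
)


@pytest.fixture
def four_leaf_tree() -> SpeciesTree:
    return read_newick(io.StringIO("((A:1,B:1):1,(C:1,D:1):1);"))


@pytest.fixture
def five_leaf_tree() -> SpeciesTree:
    return read_newick(
        io.StringIO("(((A:0.3,B:0.6):0.4,(C:0.2,D:0.9):0.1):0.5,E:1.2);")
    )


def make_mirna(locus_id="m1", species="A", chrom="chr1", start=1000,
               length=70, arm_start=5, strand="+", seq=None,
               family="") -> MirnaLocus:
    if seq is None:
        rng = random.Random(hash(locus_id) & 0xFFFF)
        seq = "".join(rng.choice("ACGU") for _ in range(length))
    return MirnaLocus(
        locus_id=locus_id, species=species, chromosome=chrom,
        start=start, end=start + len(seq) - 1, strand=strand,
        precursor=seq, mature_arms=(MatureArm(arm_start, arm_start + 21),),
        family_id=family,
    )


def make_protein(locus_id="p1", species="A", chrom="chr1", start=1,
                 end=20_000, family="PF1", exons=None,
                 strand="+") -> ProteinLocus:
    if exons is None:
        exons = ((start, start + 499), (end - 499, end))
    return ProteinLocus(
        locus_id=locus_id, species=species, chromosome=chrom, start=start,
        end=end, strand=strand, family_id=family, exons=tuple(exons),
    )


def random_binary_tree(rng: np.random.Generator, n_leaves: int) -> SpeciesTree:
    """Random topology by sequential joins, exponential branch lengths."""
    parents: list[int | None] = [None]
    lengths = [0.0]
    labels: list[str | None] = [None]
    leaves = [0]
    while len(leaves) < n_leaves:
        k = int(rng.integers(len(leaves)))
        node = leaves.pop(k)
        for _ in range(2):
            parents.append(node)
            lengths.append(float(rng.exponential(0.5)) + 0.01)
            labels.append(None)
            leaves.append(len(parents) - 1)
    for i, leaf in enumerate(sorted(leaves)):
        labels[leaf] = f"L{i}"
    return SpeciesTree.from_arrays(parents, lengths, labels)
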