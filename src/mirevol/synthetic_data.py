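"""Synthetic datasets with planted ground truth.

The generators emulate the statistical structure the downstream analyses
assume: a rooted binary species tree, Dollo-consistent family histories
(one gain, independent losses), seed-conserved precursor sequences (the
seed substitutes more slowly than the rest of the hairpin), genomes laid
out as ordered anchor sequences with planted miRNA clusters, intronic
placements and collinear blocks, and birth-death family-size histories.

Everything is a pure function of (config, seed): one integer seed is split
into independent streams per stage, so regenerating any stage is
reproducible and order-independent.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_formats import (
    MatureArm,
    MirnaLocus,
    ProfileMatrix,
    ProteinLocus,
    SpeciesTree,
    read_newick,
    write_fasta,
    write_newick,
    write_profile_matrix,
)

import pandas as pd

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_tree",
    "simulate_gain_loss",
    "simulate_sequences",
    "simulate_genomes",
    "simulate_family_sizes",
    "simulate_dataset",
    "write_bundle",
]

BASES = np.array(list("ACGU"))
MATURE_LEN = 22
SEED_LEN = 7  # mature positions 2-8


@dataclass
class SimulationConfig:
    """All knobs of the synthetic-data generators.

    Probabilities are per branch (loss) or per site per branch
    (substitution). The in-seed substitution probability must not exceed
    the off-seed one: the seed is the conserved targeting region.
    """

    seed: int = 0
    n_species: int = 10
    newick: str | None = None  # given tree; if None, Yule with yule_birth_rate
    yule_birth_rate: float = 1.0
    n_families: int = 30
    gain_root_bias: float = 0.3  # probability a family is gained at the root
    loss_prob: float = 0.1  # per-branch secondary-loss probability
    sub_off_seed: float = 0.05  # per-site substitution prob per branch
    sub_in_seed: float = 0.0
    dup_rate: float = 0.3  # expected extra copies per unit path length
    mean_cluster_size: float = 2.0  # families per planted intergenic cluster
    intra_cluster_spacing: int = 2000  # bp between loci in a cluster
    cluster_threshold: int = 10_000  # bp gap defining cluster membership
    fraction_intronic: float = 0.4
    genome_length: int = 5_000_000
    n_protein_families: int = 40
    n_inversions: int = 0
    n_translocations: int = 0
    gene_length: int = 20_000
    exon_length: int = 500

    def validate(self) -> None:
        for name in ("loss_prob", "sub_off_seed", "sub_in_seed",
                     "gain_root_bias", "fraction_intronic"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0,1]")
        if self.sub_in_seed > self.sub_off_seed:
            raise ValueError(
                "in-seed substitution probability must not exceed off-seed "
                "(seed conservation)"
            )
        if self.n_species < 2 or self.n_families < 1:
            raise ValueError("need >=2 species and >=1 family")
        if self.dup_rate < 0 or self.yule_birth_rate <= 0:
            raise ValueError("rates must be positive")


@dataclass
class GroundTruth:
    """Everything the generators planted, for use as an oracle."""

    tree: SpeciesTree
    gain_node: dict[str, int] = field(default_factory=dict)
    loss_edges: dict[str, tuple[int, ...]] = field(default_factory=dict)
    presence: ProfileMatrix | None = None
    copy_number: ProfileMatrix | None = None
    sequences: dict[str, str] = field(default_factory=dict)  # locus -> precursor
    mature: dict[str, MatureArm] = field(default_factory=dict)
    locus_family: dict[str, str] = field(default_factory=dict)
    locus_context: dict[str, str] = field(default_factory=dict)
    locus_cluster: dict[str, str] = field(default_factory=dict)
    locus_host: dict[str, str] = field(default_factory=dict)
    mirna_loci: list[MirnaLocus] = field(default_factory=list)
    protein_loci: list[ProteinLocus] = field(default_factory=list)
    anchor_order: dict[str, list[str]] = field(default_factory=dict)
    planted_blocks: list[tuple[str, ...]] = field(default_factory=list)
    genome_sizes: dict[str, int] = field(default_factory=dict)

    def family_partition(self) -> dict[str, str]:
        return dict(self.locus_family)


def _streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


# ---------------------------------------------------------------------------
# Tree
# ---------------------------------------------------------------------------


def simulate_tree(config: SimulationConfig) -> SpeciesTree:
    """Return the configured tree, or draw an ultrametric Yule tree."""
    if config.newick is not None:
        import io as _io

        return read_newick(_io.StringIO(config.newick))
    rng = _streams(config.seed, 8)[0]
    n = config.n_species
    rate = config.yule_birth_rate
    # forward Yule: start from the root split, split random lineages until n
    parents: list[int | None] = [None, 0, 0]
    birth_time = [0.0, 0.0, 0.0]
    active = [1, 2]
    t = 0.0
    while len(active) < n:
        t += rng.exponential(1.0 / (rate * len(active)))
        k = int(rng.integers(len(active)))
        node = active.pop(k)
        birth_time[node] = birth_time[node]  # keep
        i, j = len(parents), len(parents) + 1
        parents += [node, node]
        birth_time += [t, t]
        active += [i, j]
    t_end = t + rng.exponential(1.0 / (rate * len(active)))
    lengths = [0.0] * len(parents)
    labels: list[str | None] = [None] * len(parents)
    # a node's branch length = (its end time) - (its start time); for active
    # lineages the end time is t_end, for internal ones the birth time of
    # their children
    child_birth = {}
    for i, p in enumerate(parents):
        if p is not None:
            child_birth.setdefault(p, birth_time[i])
    for i in range(len(parents)):
        start = birth_time[i]
        end = child_birth.get(i, t_end)
        lengths[i] = max(end - start, 1e-6)
    lengths[0] = 0.0
    width = len(str(n))
    for idx, node in enumerate(sorted(active)):
        labels[node] = f"sp{idx + 1:0{width}d}"
    return SpeciesTree.from_arrays(parents, lengths, labels)


# ---------------------------------------------------------------------------
# Gain/loss histories
# ---------------------------------------------------------------------------


def simulate_gain_loss(
    tree: SpeciesTree, config: SimulationConfig
) -> tuple[ProfileMatrix, GroundTruth]:
    """Plant one gain node per family and independent per-branch losses.

    Each family is present exactly in the leaves of its gain clade minus the
    leaves under sampled loss edges; losses below a loss are discarded so
    the recorded loss edges are maximal. Families may go extinct (all-zero
    rows) if losses remove every leaf.
    """
    config.validate()
    rng = _streams(config.seed, 8)[1]
    species = tree.leaf_labels
    fam_width = len(str(config.n_families))
    fam_ids = [f"F{i + 1:0{fam_width}d}" for i in range(config.n_families)]
    gt = GroundTruth(tree=tree)
    presence = pd.DataFrame(0, index=fam_ids, columns=species, dtype=int)
    counts = pd.DataFrame(0, index=fam_ids, columns=species, dtype=int)
    node_ids = [n.id for n in tree.nodes]
    for fam in fam_ids:
        if rng.random() < config.gain_root_bias:
            gain = tree.root
        else:
            gain = node_ids[int(rng.integers(len(node_ids)))]
        # candidate losses on branches strictly below the gain
        below = [
            nid for nid in node_ids
            if nid != gain and gain in tree.path_to_root(nid)
        ]
        lost = {nid for nid in below if rng.random() < config.loss_prob}
        # keep only maximal loss edges (no lost ancestor)
        maximal = {
            nid for nid in lost
            if not any(a in lost for a in tree.path_to_root(nid)[1:])
        }
        present_leaves = set(tree.leaves_under(gain))
        for nid in maximal:
            present_leaves -= set(tree.leaves_under(nid))
        gt.gain_node[fam] = gain
        gt.loss_edges[fam] = tuple(sorted(maximal))
        for lid in present_leaves:
            sp = tree.nodes[lid].label
            presence.loc[fam, sp] = 1
            dist = tree.node_age(lid) - tree.node_age(gain)
            counts.loc[fam, sp] = 1 + int(rng.poisson(config.dup_rate * dist))
    gt.presence = ProfileMatrix(presence, mode="presence")
    gt.copy_number = ProfileMatrix(counts, mode="count")
    return gt.presence, gt


# ---------------------------------------------------------------------------
# Sequences
# ---------------------------------------------------------------------------


def _mutate(seq: np.ndarray, seed_mask: np.ndarray, p_off: float,
            p_in: float, rng: np.random.Generator) -> np.ndarray:
    p = np.where(seed_mask, p_in, p_off)
    hit = rng.random(len(seq)) < p
    if hit.any():
        seq = seq.copy()
        # substitute to one of the three other bases, uniformly
        shift = rng.integers(1, 4, size=int(hit.sum()))
        idx = np.searchsorted(BASES, seq[hit])
        seq[hit] = BASES[(idx + shift) % 4]
    return seq


def simulate_sequences(gt: GroundTruth, config: SimulationConfig) -> GroundTruth:
    """Evolve one ancestral precursor per family down the gain clade.

    The ancestral precursor (length 60-120, uniform composition) carries one
    mature arm; seed sites (mature offsets 2-8) substitute with
    ``sub_in_seed`` per branch, all other sites with ``sub_off_seed``.
    Within-species extra copies are recent tandem duplicates and share the
    leaf sequence. Locus ids are ``<family>_<species>_<copy>``.
    """
    rng = _streams(config.seed, 8)[2]
    tree = gt.tree
    counts = gt.copy_number.data
    for fam in counts.index:
        plen = int(rng.integers(60, 121))
        anc = BASES[rng.integers(0, 4, size=plen)]
        arm_start = int(rng.integers(1, plen - MATURE_LEN + 2))
        arm = MatureArm(arm_start, arm_start + MATURE_LEN - 1)
        seed_mask = np.zeros(plen, dtype=bool)
        seed_mask[arm_start : arm_start + SEED_LEN] = True  # offsets 2-8
        gain = gt.gain_node[fam]
        seqs_at: dict[int, np.ndarray] = {gain: anc}
        stack = [gain]
        while stack:
            nid = stack.pop()
            node = tree.nodes[nid]
            for c in node.children:
                seqs_at[c] = _mutate(
                    seqs_at[nid], seed_mask, config.sub_off_seed,
                    config.sub_in_seed, rng,
                )
                stack.append(c)
        for sp in counts.columns:
            n_copies = int(counts.loc[fam, sp])
            if n_copies == 0:
                continue
            leaf_seq = "".join(seqs_at[tree.leaf_id(sp)])
            for k in range(n_copies):
                lid = f"{fam}_{sp}_{k + 1}"
                gt.sequences[lid] = leaf_seq
                gt.mature[lid] = arm
                gt.locus_family[lid] = fam
    return gt


# ---------------------------------------------------------------------------
# Genomes (anchor order, clusters, intronic placement, synteny)
# ---------------------------------------------------------------------------


def _make_layout(gt: GroundTruth, config: SimulationConfig,
                 rng: np.random.Generator):
    """Decide the shared ancestral genome layout at the family level.

    Returns an ordered list of elements; each element is either
    ``("protein", prot_family, hosted_mirna_family_or_None)`` or
    ``("cluster", [mirna_family, ...])``.
    """
    fam_ids = list(gt.copy_number.data.index)
    rng.shuffle(fam_ids)
    n_intronic = int(round(config.fraction_intronic * len(fam_ids)))
    intronic = fam_ids[:n_intronic]
    intergenic = fam_ids[n_intronic:]
    if len(intronic) > config.n_protein_families:
        raise ValueError(
            "more intronic families than protein genes to host them"
        )
    # group intergenic families into clusters
    clusters: list[list[str]] = []
    i = 0
    while i < len(intergenic):
        size = 1 + int(rng.geometric(min(1.0, 1.0 / config.mean_cluster_size))) - 1
        size = max(1, size)
        clusters.append(intergenic[i : i + size])
        i += size
    pw = len(str(config.n_protein_families))
    prot_fams = [f"P{i + 1:0{pw}d}" for i in range(config.n_protein_families)]
    hosts = {prot_fams[i]: intronic[i] for i in range(len(intronic))}
    elements: list[tuple] = [("protein", pf, hosts.get(pf)) for pf in prot_fams]
    elements += [("cluster", tuple(c)) for c in clusters]
    order = rng.permutation(len(elements))
    return [elements[i] for i in order]


def _apply_rearrangements(order: list[int], n_inv: int, n_trans: int,
                          rng: np.random.Generator) -> tuple[list[int], list[int]]:
    """Apply inversions/translocations to an element-index order.

    Returns the new order and the set of breakpoint positions (indices into
    the ancestral order where contiguity was broken).
    """
    order = list(order)
    breakpoints: set[int] = set()
    for _ in range(n_inv):
        a, b = sorted(rng.integers(0, len(order), size=2))
        if b > a:
            order[a : b + 1] = order[a : b + 1][::-1]
            breakpoints.update({a, b + 1})
    for _ in range(n_trans):
        a, b = sorted(rng.integers(0, len(order), size=2))
        if b > a:
            seg = order[a : b + 1]
            del order[a : b + 1]
            k = int(rng.integers(0, len(order) + 1))
            order[k:k] = seg
            breakpoints.update({a, b + 1, k})
    return order, sorted(breakpoints)


def simulate_genomes(gt: GroundTruth, config: SimulationConfig) -> GroundTruth:
    """Lay each species' loci on one chromosome with planted structure.

    All species share one ancestral element order (protein genes, some
    hosting an intronic miRNA family in their central intron; intergenic
    miRNA clusters), rearranged per species by the configured number of
    inversions/translocations. Consecutive elements are separated by more
    than twice the cluster threshold, loci within a cluster by
    ``intra_cluster_spacing``, so planted cluster ids are exactly what the
    gap rule recovers.
    """
    rng = _streams(config.seed, 8)[3]
    elements = _make_layout(gt, config, rng)
    counts = gt.copy_number.data
    species = list(counts.columns)
    all_breakpoints: set[int] = set()
    element_gap = 2 * config.cluster_threshold + config.gene_length
    for sp in species:
        order, bps = _apply_rearrangements(
            list(range(len(elements))), config.n_inversions,
            config.n_translocations, rng,
        )
        all_breakpoints.update(bps)
        cursor = element_gap
        anchor_order: list[str] = []
        cluster_counter = 0
        for ei in order:
            el = elements[ei]
            if el[0] == "protein":
                _, pf, hosted = el
                g0, g1 = cursor, cursor + config.gene_length - 1
                exons = (
                    (g0, g0 + config.exon_length - 1),
                    (g1 - config.exon_length + 1, g1),
                )
                prot_id = f"{pf}_{sp}"
                gt.protein_loci.append(
                    ProteinLocus(
                        locus_id=prot_id, species=sp, chromosome="chr1",
                        start=g0, end=g1, strand="+", family_id=pf,
                        exons=exons,
                    )
                )
                anchor_order.append(pf)
                if hosted is not None and counts.loc[hosted, sp] > 0:
                    n_cop = int(counts.loc[hosted, sp])
                    pos = g0 + config.exon_length + 100
                    cluster_counter += 1
                    cid = f"{sp}_c{cluster_counter}"
                    for k in range(n_cop):
                        lid = f"{hosted}_{sp}_{k + 1}"
                        plen = len(gt.sequences[lid])
                        self_cid = cid if n_cop > 1 else ""
                        gt.locus_context[lid] = "intronic"
                        gt.locus_host[lid] = prot_id
                        gt.locus_cluster[lid] = self_cid
                        gt.mirna_loci.append(
                            MirnaLocus(
                                locus_id=lid, species=sp, chromosome="chr1",
                                start=pos, end=pos + plen - 1, strand="+",
                                precursor=gt.sequences[lid],
                                mature_arms=(gt.mature[lid],),
                                family_id=hosted,
                            )
                        )
                        anchor_order.append(hosted)
                        pos += plen + config.intra_cluster_spacing
                    if pos >= g1 - config.exon_length:
                        raise ValueError(
                            "genome too small: intron cannot hold the copies"
                        )
                cursor = g1 + 1 + element_gap
            else:
                _, fams = el
                pos = cursor
                members = []
                for fam in fams:
                    n_cop = int(counts.loc[fam, sp])
                    for k in range(n_cop):
                        members.append(f"{fam}_{sp}_{k + 1}")
                if not members:
                    continue
                cluster_counter += 1
                cid = f"{sp}_c{cluster_counter}" if len(members) > 1 else ""
                for lid in members:
                    fam = gt.locus_family[lid]
                    plen = len(gt.sequences[lid])
                    gt.locus_context[lid] = "intergenic"
                    gt.locus_cluster[lid] = cid
                    gt.mirna_loci.append(
                        MirnaLocus(
                            locus_id=lid, species=sp, chromosome="chr1",
                            start=pos, end=pos + plen - 1, strand="+",
                            precursor=gt.sequences[lid],
                            mature_arms=(gt.mature[lid],),
                            family_id=fam,
                        )
                    )
                    anchor_order.append(fam)
                    pos += plen + config.intra_cluster_spacing
                cursor = pos + element_gap
        gt.anchor_order[sp] = anchor_order
        gt.genome_sizes[sp] = max(cursor, config.genome_length)
        if cursor > config.genome_length:
            # genome length is a floor; report if the request was too small
            pass
    # planted collinear blocks: consecutive elements sit more than the
    # cluster threshold apart, so under gap-limited detection each element
    # is its own block — a host gene with its intronic miRNA family, or an
    # intergenic cluster. Tandem copies collapse to one anchor; element
    # interiors are never split because rearrangements permute whole
    # elements. Runs shorter than 2 anchors are not blocks.
    for el in elements:
        if el[0] == "protein":
            run = (el[1],) + ((el[2],) if el[2] is not None else ())
        else:
            run = tuple(el[1])
        if len(run) >= 2:
            gt.planted_blocks.append(run)
    return gt


# ---------------------------------------------------------------------------
# Birth-death family sizes
# ---------------------------------------------------------------------------


def simulate_family_sizes(
    tree: SpeciesTree,
    lam: float,
    root_sizes,
    seed: int,
) -> tuple[ProfileMatrix, dict[str, dict[int, int]]]:
    """Simulate family-size evolution by explicit birth-death events.

    Each gene independently duplicates and dies at rate ``lam`` per unit
    branch length (birth rate = death rate, the single-parameter model), so
    a lineage of size n waits Exp(2*lam*n) between events. Size 0 is
    absorbing. ``root_sizes`` maps family id to its (>=1) size at the root.

    Returns the leaf count matrix and the full per-node size history.
    """
    if lam < 0:
        raise ValueError("lam must be >= 0")
    rng = np.random.default_rng(seed)
    sizes: dict[str, dict[int, int]] = {}
    for fam, s0 in root_sizes.items():
        if s0 < 1:
            raise ValueError(f"{fam}: root size must be >= 1")
        node_size = {tree.root: int(s0)}
        for node in tree.preorder():
            if node.id == tree.root:
                continue
            n = node_size[tree.nodes[node.parent].id]
            t = node.length
            if lam > 0:
                elapsed = 0.0
                while n > 0:
                    wait = rng.exponential(1.0 / (2.0 * lam * n))
                    if elapsed + wait > t:
                        break
                    elapsed += wait
                    n += 1 if rng.random() < 0.5 else -1
            node_size[node.id] = n
        sizes[fam] = node_size
    data = pd.DataFrame(
        {
            sp: {fam: sizes[fam][tree.leaf_id(sp)] for fam in root_sizes}
            for sp in tree.leaf_labels
        }
    )
    return ProfileMatrix(data, mode="count"), sizes


# ---------------------------------------------------------------------------
# Full dataset
# ---------------------------------------------------------------------------


def simulate_dataset(config: SimulationConfig) -> GroundTruth:
    """Run all generators in order and return the complete ground truth."""
    config.validate()
    tree = simulate_tree(config)
    _, gt = simulate_gain_loss(tree, config)
    simulate_sequences(gt, config)
    simulate_genomes(gt, config)
    return gt


def stripped_loci(gt: GroundTruth) -> list[MirnaLocus]:
    """The miRNA loci as the pipeline first sees them: no family labels."""
    return [dataclasses.replace(l, family_id="", context="", cluster_id="")
            for l in gt.mirna_loci]


def write_bundle(gt: GroundTruth, outdir) -> None:
    """Write the dataset in the formats the readers consume, plus truth TSVs."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_newick(gt.tree, out / "tree.nwk")
    write_fasta(dict(sorted(gt.sequences.items())), out / "precursors.fasta")
    with open(out / "loci.gff3", "w") as fh:
        fh.write("##gff-version 3\n")
        for l in sorted(gt.mirna_loci, key=lambda x: x.locus_id):
            arms = ",".join(f"{a.start}-{a.end}" for a in l.mature_arms)
            fh.write(
                f"{l.chromosome}\tsim\tmirna\t{l.start}\t{l.end}\t.\t"
                f"{l.strand}\t.\tID={l.locus_id};species={l.species};"
                f"mature={arms}\n"
            )
        for p in sorted(gt.protein_loci, key=lambda x: x.locus_id):
            ex = ",".join(f"{a}-{b}" for a, b in p.exons)
            fh.write(
                f"{p.chromosome}\tsim\tprotein\t{p.start}\t{p.end}\t.\t"
                f"{p.strand}\t.\tID={p.locus_id};species={p.species};"
                f"family={p.family_id};exons={ex}\n"
            )
    with open(out / "reference_families.tsv", "w") as fh:
        fh.write("locus_id\tfamily_id\n")
        for lid in sorted(gt.locus_family):
            fh.write(f"{lid}\t{gt.locus_family[lid]}\n")
    with open(out / "genome_sizes.tsv", "w") as fh:
        fh.write("species\tgenome_size\n")
        for sp in sorted(gt.genome_sizes):
            fh.write(f"{sp}\t{gt.genome_sizes[sp]}\n")
    if gt.presence is not None:
        write_profile_matrix(gt.presence, out / "truth_presence.tsv")
    if gt.copy_number is not None:
        write_profile_matrix(gt.copy_number, out / "truth_counts.tsv")
    with open(out / "truth_context.tsv", "w") as fh:
        fh.write("locus_id\tcontext\tcluster_id\thost\n")
        for lid in sorted(gt.locus_context):
            fh.write(
                f"{lid}\t{gt.locus_context[lid]}\t"
                f"{gt.locus_cluster.get(lid, '')}\t{gt.locus_host.get(lid, '')}\n"
            )
    with open(out / "truth_gains.tsv", "w") as fh:
        fh.write("family\tgain_node\tloss_edges\n")
        for fam in sorted(gt.gain_node):
            losses = ",".join(str(e) for e in gt.loss_edges.get(fam, ()))
            fh.write(f"{fam}\t{gt.gain_node[fam]}\t{losses}\n")
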