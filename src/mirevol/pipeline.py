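"""End-to-end pipeline: families -> profiles -> dollo -> expansions ->
coevolution -> synteny, with a manifest recording parameters, seed and
input checksums. Rerunning with the same config and seed is byte-identical
for every TSV output."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .coevolution import results_to_frame, screen_pairs
from .dollo import annotate_tree_figure, dollo_reconstruct, node_statistics
from .expansions import expansion_report, root_present_families
from .families import (
    FamilyPartition,
    ScoringScheme,
    all_vs_all_scores,
    mark_seed,
    optimize_threshold,
    single_linkage,
)
from .io_formats import (
    ProfileMatrix,
    read_loci,
    read_newick,
    write_profile_matrix,
)
from .profiles import (
    annotate_context,
    assign_clusters,
    build_matrices,
    family_context_flags,
    render_family_glyph,
)
from .synteny import (
    SyntenyParams,
    build_anchors,
    chain_blocks,
    classify_and_measure,
    detect_blocks,
)

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]


@dataclass
class PipelineConfig:
    """Paths and per-stage parameters for a full run."""

    tree: str = ""
    loci: str = ""
    fasta: str = ""
    reference_families: str = ""  # optional; enables threshold optimisation
    genome_sizes: str = ""  # optional TSV species\tgenome_size
    outdir: str = "mirevol_out"
    seed: int = 0
    # families
    match: float = 5.0
    mismatch: float = -4.0
    gap_open: float = -10.0
    gap_extend: float = -2.0
    seed_multiplier: float = 2.0
    fixed_threshold: float | None = None  # used when no reference given
    # profiles
    cluster_threshold: int = 10_000
    # expansions
    expansion_n_sim: int = 500
    expansion_max_size: int = 100
    # coevolution
    coevolve_min_present: int = 5
    coevolve_min_absent: int = 5
    coevolve_top_families: int = 10
    coevolve_restarts: int = 2
    # synteny
    synteny_max_gap: int = 10_000
    synteny_min_regions: int = 2
    synteny_min_anchors: int = 2
    synteny_max_mismatch: int = 10

    def validate(self) -> None:
        for name in ("tree", "loci", "fasta"):
            p = getattr(self, name)
            if not p or not Path(p).exists():
                raise ValueError(f"config path {name!r} missing: {p!r}")
        for name in ("reference_families", "genome_sizes"):
            p = getattr(self, name)
            if p and not Path(p).exists():
                raise ValueError(f"config path {name!r} does not exist: {p!r}")
        if self.reference_families == "" and self.fixed_threshold is None:
            raise ValueError(
                "need either a reference family table (threshold "
                "optimisation) or a fixed_threshold"
            )


def load_config(path) -> PipelineConfig:
    """Flat key=value config file (lines; # comments; section headers
    ignored). CLI flags override these values."""
    cfg = PipelineConfig()
    types = {f.name: f.type for f in dataclasses.fields(PipelineConfig)}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("["):
                continue
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config key {key!r}")
            current = getattr(cfg, key)
            if isinstance(current, bool):
                setattr(cfg, key, value.lower() in ("1", "true", "yes"))
            elif isinstance(current, int):
                setattr(cfg, key, int(value))
            elif isinstance(current, float) or key == "fixed_threshold":
                setattr(cfg, key, float(value))
            else:
                setattr(cfg, key, value)
    return cfg


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g",
              lineterminator="\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage in order; returns the manifest dict.

    A stage failure raises with the stage named; outputs written so far
    are left in place.
    """
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": dataclasses.asdict(config),
        "inputs": {},
        "outputs": [],
        "stages": [],
    }
    for name in ("tree", "loci", "fasta", "reference_families",
                 "genome_sizes"):
        p = getattr(config, name)
        if p:
            manifest["inputs"][name] = {"path": p, "sha256": _sha256(p)}

    def emit(df, filename, index=True):
        _write_tsv(df, out / filename, index=index)
        manifest["outputs"].append(filename)

    def stage(name):
        manifest["stages"].append(name)
        return name

    try:
        stage("load")
        tree = read_newick(config.tree)
        mirna_loci, protein_loci, rejected = read_loci(
            config.loci, config.fasta, fmt="gff3"
        )
        if rejected:
            (out / "rejected_loci.txt").write_text("\n".join(rejected) + "\n")
            manifest["outputs"].append("rejected_loci.txt")

        stage("families")
        scheme = ScoringScheme(
            match=config.match, mismatch=config.mismatch,
            gap_open=config.gap_open, gap_extend=config.gap_extend,
            seed_multiplier=config.seed_multiplier,
        )
        marked = [mark_seed(l) for l in mirna_loci]
        scores = all_vs_all_scores(marked, scheme)
        if config.reference_families:
            ref_df = pd.read_csv(config.reference_families, sep="\t")
            ref_sets: dict[str, set] = {}
            for _, row in ref_df.iterrows():
                ref_sets.setdefault(row["family_id"], set()).add(
                    row["locus_id"])
            reference = FamilyPartition.from_sets(ref_sets.values())
            threshold, partition, distance = optimize_threshold(
                scores, reference)
        else:
            threshold = float(config.fixed_threshold)
            partition = single_linkage(scores, threshold)
            distance = None
        part_df = pd.DataFrame(
            sorted(partition.assignment.items()),
            columns=["locus_id", "family_id"],
        )
        emit(part_df, "partition.tsv", index=False)
        (out / "threshold.json").write_text(
            json.dumps({"threshold": threshold,
                        "split_join_to_reference": distance,
                        "n_families": partition.n_families()},
                       indent=2) + "\n"
        )
        manifest["outputs"].append("threshold.json")

        stage("profiles")
        presence, counts = build_matrices(mirna_loci, partition, tree)
        write_profile_matrix(presence, out / "presence.tsv")
        write_profile_matrix(counts, out / "counts.tsv")
        manifest["outputs"] += ["presence.tsv", "counts.tsv"]
        context = annotate_context(mirna_loci, protein_loci)
        clusters = assign_clusters(mirna_loci, config.cluster_threshold)
        annotation = context.merge(clusters)
        emit(annotation.to_frame(), "context.tsv")
        glyph = render_family_glyph(counts, svg_path=out / "glyphs.svg")
        emit(glyph, "glyph_legend.tsv", index=False)
        manifest["outputs"].append("glyphs.svg")

        stage("dollo")
        nonzero = presence.data.index[presence.data.sum(axis=1) > 0]
        presence_nz = ProfileMatrix(presence.data.loc[nonzero],
                                    mode="presence")
        rec = dollo_reconstruct(presence_nz, tree)
        emit(rec.to_frame(), "gains.tsv")
        fam_intronic, fam_clustered = family_context_flags(
            mirna_loci, partition, annotation)
        stats = node_statistics(rec, tree, fam_intronic, fam_clustered)
        emit(stats.table, "node_stats.tsv")
        branch_tab = annotate_tree_figure(stats, tree, rec,
                                          svg_path=out / "tree.svg")
        emit(branch_tab, "tree_annotation.tsv")
        manifest["outputs"].append("tree.svg")

        stage("expansions")
        root_fams = root_present_families(counts, tree)
        if root_fams:
            exp = expansion_report(
                ProfileMatrix(counts.data.loc[root_fams], mode="count"),
                tree, n_sim=config.expansion_n_sim, seed=config.seed,
                max_size=config.expansion_max_size,
            )
            emit(exp, "expansions.tsv")

        stage("coevolution")
        variability = (
            presence_nz.data.var(axis=1).sort_values(ascending=False)
        )
        top = sorted(variability.index[: config.coevolve_top_families])
        coe = screen_pairs(
            ProfileMatrix(presence_nz.data.loc[top], mode="presence"),
            None, tree,
            min_present=config.coevolve_min_present,
            min_absent=config.coevolve_min_absent,
            n_restarts=config.coevolve_restarts, seed=config.seed,
        )
        emit(results_to_frame(coe), "coevolution.tsv", index=False)

        stage("synteny")
        labelled = [l if l.family_id else l.with_family(
            partition.assignment[l.locus_id]) for l in mirna_loci]
        anchors = build_anchors(labelled, protein_loci, partition)
        params = SyntenyParams(
            max_gap_length=config.synteny_max_gap,
            min_regions=config.synteny_min_regions,
            min_anchors=config.synteny_min_anchors,
            max_mismatch_anchors=config.synteny_max_mismatch,
        )
        blocks = chain_blocks(detect_blocks(anchors, params))
        kinds = {partition.assignment[l.locus_id]: "mirna"
                 for l in mirna_loci}
        kinds.update({p.family_id: "protein" for p in protein_loci})
        if config.genome_sizes:
            gs = pd.read_csv(config.genome_sizes, sep="\t")
            genome_sizes = dict(zip(gs["species"], gs["genome_size"]))
        else:
            genome_sizes = {}
            for l in list(mirna_loci) + list(protein_loci):
                genome_sizes[l.species] = max(
                    genome_sizes.get(l.species, 0), l.end)
        measures = classify_and_measure(blocks, kinds, genome_sizes)
        emit(measures, "synteny_blocks.tsv", index=False)
    except Exception as exc:
        failed = manifest["stages"][-1] if manifest["stages"] else "setup"
        raise RuntimeError(f"pipeline failed in stage {failed!r}: {exc}") \
            from exc

    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
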