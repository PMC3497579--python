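"""Detect and characterise conserved synteny blocks.

Builds the combined miRNA + protein anchor dataset, detects collinear
blocks (gap <= 10 kb, >= 2 anchors in >= 2 regions), chains blocks
sharing terminal anchors, classifies them (protein-only / mixed / miRNA-
only), tabulates genome-size-normalised length distributions and renders
a display alignment of the largest miRNA-containing block. Outputs under
results/synteny/.
"""

import pandas as pd
from common import DATA, outdir

from mirevol.families import FamilyPartition
from mirevol.io_formats import read_loci
from mirevol.profiles import annotate_context
from mirevol.synteny import (align_blocks_for_display, build_anchors,
                             chain_blocks, classify_and_measure,
                             cumulative_length_table, detect_blocks)


def main() -> None:
    out = outdir("synteny")
    mirna_loci, protein_loci, _ = read_loci(DATA / "loci.gff3",
                                            DATA / "precursors.fasta")
    part_df = pd.read_csv(outdir("families") / "partition.tsv", sep="\t")
    partition = FamilyPartition(dict(zip(part_df.locus_id,
                                         part_df.family_id)))
    labelled = [l.with_family(partition.assignment[l.locus_id])
                for l in mirna_loci]
    anchor_seqs = build_anchors(labelled, protein_loci, partition)
    blocks = chain_blocks(detect_blocks(anchor_seqs))
    kinds = {partition.assignment[l.locus_id]: "mirna" for l in mirna_loci}
    kinds.update({p.family_id: "protein" for p in protein_loci})
    sizes = pd.read_csv(DATA / "genome_sizes.tsv", sep="\t")
    genome_sizes = dict(zip(sizes.species, sizes.genome_size))
    measures = classify_and_measure(blocks, kinds, genome_sizes)
    measures.to_csv(out / "blocks.tsv", sep="\t", index=False)
    cumulative_length_table(measures).to_csv(
        out / "normalized_lengths.tsv", sep="\t", index=False)
    by_class = measures.groupby("class")["block_id"].nunique()
    print(f"{measures.block_id.nunique()} blocks over "
          f"{len(anchor_seqs)} genomes:")
    for cls, n in by_class.items():
        print(f"  {cls}: {n}")
    mirna_blocks = [b for b in blocks if b.block_class != "protein_only"
                    and len(b.occurrences) >= 2]
    if mirna_blocks:
        big = max(mirna_blocks, key=lambda b: b.n_anchors)
        intronic = {
            lid for lid, ctx in annotate_context(
                mirna_loci, protein_loci).context.items()
            if ctx == "intronic"
        }
        lists = {s.key: s.anchors for s in anchor_seqs}
        align_blocks_for_display(big, lists, svg_path=out / "block.svg",
                                 intronic_loci=intronic)
        print(f"display alignment of {big.block_id} "
              f"({big.n_anchors} anchors, {len(big.occurrences)} "
              f"occurrences) -> block.svg")


if __name__ == "__main__":
    main()
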