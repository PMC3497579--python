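"""Reconstruct family gains and losses by Dollo parsimony.

Each family is gained once at the MRCA of its presence leaves; maximal
presence-free subtrees below the gain are losses. Per-node statistics
(age, gains, cumulative gains, context fractions) and the annotated tree
figure go under results/dollo/.
"""

import pandas as pd
from common import DATA, outdir

from mirevol.dollo import (annotate_tree_figure, dollo_reconstruct,
                           node_statistics)
from mirevol.families import FamilyPartition
from mirevol.io_formats import read_loci, read_newick, read_profile_matrix
from mirevol.profiles import (annotate_context, assign_clusters,
                              family_context_flags)


def main() -> None:
    out = outdir("dollo")
    tree = read_newick(DATA / "tree.nwk")
    presence = read_profile_matrix(outdir("profiles") / "presence.tsv")
    mirna_loci, protein_loci, _ = read_loci(DATA / "loci.gff3",
                                            DATA / "precursors.fasta")
    part_df = pd.read_csv(outdir("families") / "partition.tsv", sep="\t")
    partition = FamilyPartition(dict(zip(part_df.locus_id,
                                         part_df.family_id)))
    rec = dollo_reconstruct(presence, tree)
    rec.to_frame().to_csv(out / "gains.tsv", sep="\t")
    annotation = annotate_context(mirna_loci, protein_loci).merge(
        assign_clusters(mirna_loci))
    fam_int, fam_clu = family_context_flags(mirna_loci, partition,
                                            annotation)
    stats = node_statistics(rec, tree, fam_int, fam_clu)
    stats.table.to_csv(out / "node_stats.tsv", sep="\t")
    branch_tab = annotate_tree_figure(stats, tree, rec,
                                      svg_path=out / "tree.svg")
    branch_tab.to_csv(out / "tree_annotation.tsv", sep="\t")
    total_losses = sum(rec.loss_count(f) for f in rec.families)
    root_gains = stats.table.loc[tree.root, "n_gains"]
    print(f"{len(rec.families)} families reconstructed: "
          f"{root_gains} gained at the root, "
          f"{total_losses} secondary losses in total")
    oldest = stats.table[stats.table.n_gains > 0].sort_values("age")
    print("gains by node age (first 5 nodes):")
    print(oldest[["age", "n_gains", "cumulative_gains", "pct_intronic",
                  "pct_clustered"]].head().to_string())


if __name__ == "__main__":
    main()
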