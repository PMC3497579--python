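"""Build profile matrices and annotate genomic context.

Counts loci per family and species, classifies each locus intronic vs
intergenic, chains loci into genomic clusters (10 kb gap rule) and renders
the copy-number glyph grid. Writes matrices and tables under
results/profiles/.
"""

import pandas as pd
from common import DATA, outdir

from mirevol.families import FamilyPartition
from mirevol.io_formats import read_loci, read_newick, write_profile_matrix
from mirevol.profiles import (annotate_context, assign_clusters,
                              build_matrices, render_family_glyph)


def main() -> None:
    out = outdir("profiles")
    tree = read_newick(DATA / "tree.nwk")
    mirna_loci, protein_loci, _ = read_loci(DATA / "loci.gff3",
                                            DATA / "precursors.fasta")
    part_df = pd.read_csv(outdir("families") / "partition.tsv", sep="\t")
    partition = FamilyPartition(dict(zip(part_df.locus_id,
                                         part_df.family_id)))
    presence, counts = build_matrices(mirna_loci, partition, tree)
    write_profile_matrix(presence, out / "presence.tsv")
    write_profile_matrix(counts, out / "counts.tsv")
    context = annotate_context(mirna_loci, protein_loci)
    clusters = assign_clusters(mirna_loci)
    annotation = context.merge(clusters)
    annotation.to_frame().to_csv(out / "context.tsv", sep="\t")
    legend = render_family_glyph(counts, svg_path=out / "glyphs.svg")
    legend.to_csv(out / "glyph_legend.tsv", sep="\t", index=False)
    n = len(mirna_loci)
    n_int = sum(1 for v in context.context.values() if v == "intronic")
    n_clu = sum(1 for l in mirna_loci if clusters.is_clustered(l.locus_id))
    print(f"{n} loci: {100 * n_int / n:.0f}% intronic, "
          f"{100 * n_clu / n:.0f}% in clusters (gap <= 10 kb)")
    print(f"matrix: {len(counts.families)} families x "
          f"{len(counts.species)} species, "
          f"total copies {int(counts.data.to_numpy().sum())}")


if __name__ == "__main__":
    main()
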