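"""Generate the synthetic study dataset.

Writes the full input bundle (species tree, precursor FASTA, locus GFF3,
reference families, genome sizes) plus the planted ground truth tables
under results/data/, and prints the dataset's headline numbers.
"""

from common import DATA, STUDY_CONFIG

from mirevol.synthetic_data import simulate_dataset, write_bundle


def main() -> None:
    gt = simulate_dataset(STUDY_CONFIG)
    write_bundle(gt, DATA)
    n_present = int(gt.presence.data.to_numpy().sum())
    n_intronic = sum(1 for v in gt.locus_context.values()
                     if v == "intronic")
    n_clustered = sum(1 for v in gt.locus_cluster.values() if v)
    print(f"dataset written to {DATA}")
    print(f"  species: {STUDY_CONFIG.n_species}, "
          f"families: {STUDY_CONFIG.n_families}")
    print(f"  miRNA loci: {len(gt.mirna_loci)} "
          f"({n_intronic} intronic, {n_clustered} in clusters)")
    print(f"  protein loci: {len(gt.protein_loci)}")
    print(f"  family-species presences: {n_present}")
    print(f"  planted collinear blocks: {len(gt.planted_blocks)}")


if __name__ == "__main__":
    main()
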