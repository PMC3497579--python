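"""Attribute miRNA loci to families.

All-vs-all seed-weighted global alignment, then single-linkage clustering
at the threshold minimising the split-join distance to the reference
(planted) families. Writes the partition and score summary under
results/families/.
"""

import json

import pandas as pd
from common import DATA, outdir

from mirevol.families import (FamilyPartition, all_vs_all_scores, mark_seed,
                              optimize_threshold)
from mirevol.io_formats import read_loci


def main() -> None:
    out = outdir("families")
    mirna_loci, _, rejected = read_loci(DATA / "loci.gff3",
                                        DATA / "precursors.fasta")
    assert not rejected, rejected
    marked = [mark_seed(l) for l in mirna_loci]
    scores = all_vs_all_scores(marked)
    ref = pd.read_csv(DATA / "reference_families.tsv", sep="\t")
    sets: dict[str, set] = {}
    for _, row in ref.iterrows():
        sets.setdefault(row["family_id"], set()).add(row["locus_id"])
    reference = FamilyPartition.from_sets(sets.values())
    threshold, partition, distance = optimize_threshold(scores, reference)
    pd.DataFrame(sorted(partition.assignment.items()),
                 columns=["locus_id", "family_id"]).to_csv(
        out / "partition.tsv", sep="\t", index=False)
    (out / "threshold.json").write_text(json.dumps(
        {"threshold": threshold, "split_join_to_reference": distance,
         "n_families": partition.n_families()}, indent=2) + "\n")
    print(f"{len(mirna_loci)} loci -> {partition.n_families()} families "
          f"at score threshold {threshold:g}")
    print(f"split-join distance to reference families: {distance}")


if __name__ == "__main__":
    main()
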