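"""Screen phylogenetic-profile pairs for correlated evolution.

Tests miRNA family presence/absence pairs (most variable families) with
the 4-state dependent vs independent likelihood-ratio test. Writes the
ranked table under results/coevolution/.
"""

from common import DATA, STUDY_SEED, outdir

from mirevol.coevolution import results_to_frame, screen_pairs
from mirevol.io_formats import ProfileMatrix, read_newick, \
    read_profile_matrix


def main() -> None:
    out = outdir("coevolution")
    tree = read_newick(DATA / "tree.nwk")
    presence = read_profile_matrix(outdir("profiles") / "presence.tsv")
    variability = presence.data.var(axis=1).sort_values(ascending=False)
    top = sorted(variability.index[:10])
    matrix = ProfileMatrix(presence.data.loc[top], mode="presence")
    results = screen_pairs(matrix, None, tree, min_present=3,
                           min_absent=3, n_restarts=3, seed=STUDY_SEED)
    frame = results_to_frame(results)
    frame.to_csv(out / "coevolution.tsv", sep="\t", index=False)
    tested = frame[frame.passed_filter]
    n_sig = int(tested["significant"].sum())
    print(f"{len(frame)} pairs, {len(tested)} passed the presence filter, "
          f"{n_sig} significant at the chi-square(4) 0.999 level")
    print("largest likelihood ratios:")
    print(tested[["trait_a", "trait_b", "likelihood_ratio"]]
          .head().to_string(index=False))


if __name__ == "__main__":
    main()
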