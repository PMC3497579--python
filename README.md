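# mirevol

Comparative genomics of microRNA families across species. The package
takes miRNA precursor loci (with mature-arm annotation), protein-coding
loci with family labels, and a rooted binary species phylogram, and runs
the full analysis chain a cross-species miRNA evolution study needs:

1. **Family attribution** — all-vs-all global (Needleman–Wunsch)
   alignment of precursor stem-loops under a scoring scheme that doubles
   the reward for matches inside the seed (mature positions 2–8, encoded
   as an expanded alphabet); single-linkage clustering of the scores; the
   clustering threshold chosen by minimising the van Dongen split-join
   distance to a reference partition,
   d(A,B) = (n − Σ_{C∈A} max_{D∈B}|C∩D|) + (n − Σ_{D∈B} max_{C∈A}|D∩C|).
2. **Profiles and genomic context** — family × species presence and
   copy-number matrices; intronic vs intergenic classification (strict
   containment in a host gene, no exon overlap); genomic miRNA clusters by
   a 10 kb single-linkage gap rule; copy-number glyphs (white 0, rainbow
   1–9, black ≥ 10).
3. **Dollo parsimony** — each family is gained once at the MRCA of its
   presence leaves; losses are the maximal presence-free subtrees below
   the gain. Node age (root-to-node branch length) dates each family's
   birth; per-node statistics track gains, cumulative gains, and the
   intronic/clustered fraction of appearing families.
4. **Expansions** — family sizes evolve by a linear birth–death process
   with equal per-gene birth and death rate λ;
   P(c|s,t) = Σ_j C(s,j) C(s+c−j−1, s−1) α^{s+c−2j}(1−2α)^j with
   α = λt/(1+λt). A single λ is fitted by maximum likelihood (pruning
   over ancestral sizes, uniform root-size prior over 1..max), and
   per-family expansion p-values are conditional Monte-Carlo under the
   fitted model.
5. **Correlated evolution** — pairs of binary phylogenetic profiles are
   tested with Pagel-style continuous-time Markov chains on
   {00,01,10,11}: 4-rate independent vs 8-rate dependent model, both fit
   by maximum likelihood (Felsenstein pruning, stationary root), ranked
   by LR = 2(lnL_dep − lnL_ind) against χ²(4 df).
6. **Synteny** — miRNA and protein loci become family-labelled anchors;
   a greedy deterministic detector finds maximal collinear anchor runs
   shared by ≥ 2 genome regions (same order or fully reversed, ≤ 10 kb
   between shared anchors, up to 10 non-shared insertions); blocks
   sharing a terminal anchor are chained; blocks are classed
   protein-only / mixed / miRNA-only and their lengths normalised by
   genome size.

Real multi-genome annotation sets are large downloads, so the package
ships a first-class synthetic-data generator
(`mirevol.synthetic_data`) that plants a complete ground truth — gain
nodes, loss edges, copy numbers, seed-conserved sequences, cluster and
intron placement, collinear blocks — against which every stage is tested.

## Worked example

The numbered drivers under `analysis/` run the whole study on a 12-species,
40-family synthetic dataset and write their tables under `results/`:

```sh
cd analysis
python 01_simulate_dataset.py
python 02_cluster_families.py
...
python 07_synteny.py
```

`01` prints the dataset it planted:

```
  species: 12, families: 40
  miRNA loci: 241 (97 intronic, 179 in clusters)
  protein loci: 480
```

`02` recovers the planted families exactly — 241 loci fall into 40
families at alignment-score threshold 255, split-join distance 0 to the
reference. `03` reports the context mix (40% intronic, 74% clustered at
the 10 kb rule). `04` reconstructs the histories: 14 families gained at
the root, 23 secondary losses, with per-node age/cumulative-gain tables.
`05` fits the birth–death rate to the root-present families and gets
λ̂ = 0.507 events per gene per unit branch length (the generator used
λ = 0.5 via its duplication settings; no family reaches p < 0.01, as
none was planted as an expansion). `06` screens 45 profile pairs and
finds no significant association (largest LR 8.2, below the χ²(4)
0.999 cutoff of 18.5 — the dataset plants no co-evolving pair). `07`
detects 14 synteny blocks (9 mixed, 5 miRNA-only) and renders a
family-coloured block alignment.

The same pipeline is exposed as a CLI:

```sh
mirevol simulate --seed 3 --n-species 8 --n-families 20 --out bundle/
mirevol run --bundle bundle/ --out out/ --seed 3
```

`mirevol run` writes every stage's TSV plus a `manifest.json` recording
parameters, seed and input checksums; reruns with the same seed are
byte-identical.

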