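"""Shared settings for the analysis drivers.

One synthetic study dataset stands in for the multi-genome miRNA/protein
annotation set the pipeline is designed for: 12 species, 40 miRNA
families with Dollo-consistent histories, seed-conserved precursors,
clustered/intronic genomic placement and planted collinear blocks.
"""

from pathlib import Path

from mirevol.synthetic_data import SimulationConfig

RESULTS = Path(__file__).resolve().parents[1] / "results"
DATA = RESULTS / "data"

STUDY_SEED = 2026

STUDY_CONFIG = SimulationConfig(
    seed=STUDY_SEED,
    n_species=12,
    n_families=40,
    gain_root_bias=0.3,
    loss_prob=0.1,
    sub_off_seed=0.05,
    sub_in_seed=0.0,
    dup_rate=0.3,
    mean_cluster_size=2.0,
    fraction_intronic=0.4,
    n_protein_families=40,
)


def outdir(name: str) -> Path:
    d = RESULTS / name
    d.mkdir(parents=True, exist_ok=True)
    return d
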