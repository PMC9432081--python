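import numpy as np
import pandas as pd
import pytest

from methlink import synthdata
from methlink.synthdata import SimConfig


def small_config(seed: int = 5, **overrides) -> SimConfig:
    defaults = dict(seed=seed, n_chrom=1, chrom_length=60_000, n_genes=15,
                    gene_length_range=(600, 1500), depth=20.0,
                    control_chrom_length=5_000)
    defaults.update(overrides)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def small_study():
    """One small simulated study with planted DMRs and DEGs."""
    cfg = small_config()
    _, genes = synthdata.generate_genome(cfg)
    linked = {"CG": [genes["gene_id"].iloc[2]],
              "CHG": [genes["gene_id"].iloc[7]],
              "CHH": [genes["gene_id"].iloc[11]]}
    cfg.planted_dmrs = synthdata.make_planted_dmrs(
        cfg, genes, n_unlinked={"CG": 2, "CHG": 2, "CHH": 2},
        delta={"CG": -0.35, "CHG": 0.35, "CHH": 0.25}, linked_genes=linked)
    cfg.planted_degs = [
        synthdata.PlantedDEG(linked["CG"][0], 3.0, "up"),
        synthdata.PlantedDEG(linked["CHG"][0], -3.0, "down"),
        synthdata.PlantedDEG(linked["CHH"][0], 3.0, "up"),
        synthdata.PlantedDEG(genes["gene_id"].iloc[0], 3.0, "up"),
    ]
    genome, genes = synthdata.generate_genome(cfg)
    reports, truth_dmrs = synthdata.generate_methylome(cfg, genome, genes)
    counts, sheet, truth_degs = synthdata.generate_counts(cfg, genes)
    return {"cfg": cfg, "genome": genome, "genes": genes,
            "reports": reports, "truth_dmrs": truth_dmrs,
            "counts": counts, "sample_sheet": sheet,
            "truth_degs": truth_degs,
            "chrom_lengths": {c: len(s) for c, s in genome.items()
                              if c != synthdata.CONTROL_CHROM}}


@pytest.fixture()
def toy_report() -> pd.DataFrame:
    """Hand-written cytosine records covering all contexts and strands."""
    return pd.DataFrame({
        "chrom": ["chr1"] * 6,
        "pos": [10, 25, 40, 55, 70, 85],
        "strand": ["+", "-", "+", "-", "+", "+"],
        "meth": [3, 1, 4, 0, 2, 8],
        "unmeth": [1, 3, 0, 4, 2, 0],
        "context": ["CG", "CG", "CHG", "CHH", "CHH", "CG"],
        "tri": ["CGT", "CGA", "CAG", "CTT", "CAT", "CGG"],
    })


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
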