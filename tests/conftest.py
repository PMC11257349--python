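import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles helper module

from neowscan import FusionEvent, SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def fused_sim():
    """Default-condition simulation: 2-species clade, fusion on chr4."""
    return simulate_dataset(SimConfig(seed=101))


@pytest.fixture(scope="session")
def fused_scan(fused_sim):
    from neowscan import scan_for_fusions

    cfg = fused_sim.config
    lengths = {c: cfg.chrom_length(c) for c in cfg.chrom_names}
    return scan_for_fusions(
        fused_sim.table, fused_sim.sheet, cfg.fused_clade, lengths
    )


@pytest.fixture(scope="session")
def tiny_sim():
    """Small fused dataset for I/O and genealogy unit tests."""
    cfg = SimConfig(
        n_chromosomes=2,
        chrom_length_bp=500_000,
        n_background_sites_per_chrom=4_000,
        samples_per_species_per_sex=3,
        fusion_events=(FusionEvent("chr1", 40_000_000.0),),
        speciation_age_generations=10_000_000.0,
        p_degenerate=0.0,
        seed=42,
    )
    return simulate_dataset(cfg)
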