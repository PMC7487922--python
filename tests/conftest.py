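"""Shared fixtures: one small synthetic study reused across test modules."""
from __future__ import annotations

import pandas as pd
import pytest

from editome.config import DetectionConfig, SimConfig
from editome import detection, synthetic

TINY = dict(
    seed=7,
    genome_length=30_000,
    n_genes=4,
    n_true_sites=60,
    n_het_snps=10,
    n_read_end_artifacts=6,
    n_homopolymer_artifacts=6,
    n_mismap_artifacts=6,
    n_background_sites=30,
    coverage_mean=40.0,
    base_error_rate=0.0,
    flank_energy_mirnas=9,
)


@pytest.fixture(scope="session")
def tiny_config() -> SimConfig:
    return SimConfig(**TINY)


@pytest.fixture(scope="session")
def tiny_ref(tiny_config):
    return synthetic.generate_reference(tiny_config)


@pytest.fixture(scope="session")
def tiny_truth(tiny_config, tiny_ref):
    return synthetic.plant_truth(tiny_ref, tiny_config)


@pytest.fixture(scope="session")
def tiny_bundle(tiny_ref, tiny_truth):
    """Reference bundle with the simulated DNA variation loaded."""
    tiny_ref.wgs_genotypes = {(s.chrom, s.pos): "het" for s in tiny_truth.het_snps}
    tiny_ref.known_snps = {(s.chrom, s.pos) for s in tiny_truth.het_snps}
    return tiny_ref


@pytest.fixture(scope="session")
def tiny_evidence(tiny_config, tiny_bundle, tiny_truth) -> pd.DataFrame:
    ev, _ = synthetic.simulate_rna_evidence(tiny_bundle, tiny_truth, tiny_config)
    return pd.concat(ev.values(), ignore_index=True).sort_values(
        ["chrom", "pos", "sample_id", "read_id"]
    ).reset_index(drop=True)


@pytest.fixture(scope="session")
def tiny_realized_levels(tiny_config, tiny_bundle, tiny_truth) -> pd.DataFrame:
    _, levels = synthetic.simulate_rna_evidence(tiny_bundle, tiny_truth, tiny_config)
    return levels


@pytest.fixture(scope="session")
def tiny_calls(tiny_bundle, tiny_evidence):
    cfg = DetectionConfig()
    calls = detection.call_candidates(tiny_evidence, tiny_bundle, cfg)
    calls, attrition = detection.apply_filters(calls, tiny_bundle, tiny_evidence, cfg)
    return calls, attrition


@pytest.fixture(scope="session")
def tiny_sites(tiny_calls):
    sites, _counts, _pct = detection.select_editing_sites(tiny_calls[0])
    return sites
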