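"""Shared fixtures: small simulated datasets built once per session."""

import numpy as np
import pytest

from ddradmap.config import config_from_dict
from ddradmap.pipeline import run_pipeline
from ddradmap.simulate import SimConfig, simulate_dataset


def small_sim_overrides(**kw):
    """A fast, fully read-tiled simulation (fragments <= 2 read windows)."""
    base = dict(n_chromosomes=2, chrom_length_cM=50.0, n_tags=60,
                snp_rate=0.01, paralog_fraction=0.0, repeat_copies=0,
                n_individuals=30, mean_depth=12, parent_mean_depth=20,
                error_rate=0.0, insert_window=(200, 240),
                min_snps_per_tag=1, seed=42)
    base.update(kw)
    return base


@pytest.fixture(scope="session")
def clean_dataset(tmp_path_factory):
    """Error-free simulated pools + truth, shared across read-level tests."""
    outdir = tmp_path_factory.mktemp("clean_sim")
    config = SimConfig(**small_sim_overrides())
    truth, manifest = simulate_dataset(config, outdir)
    return config, truth, manifest


@pytest.fixture(scope="session")
def clean_pipeline_result(tmp_path_factory):
    """Full pipeline run on an error-free simulation."""
    outdir = tmp_path_factory.mktemp("clean_run")
    cfg = config_from_dict({
        "mode": "simulate", "outdir": str(outdir), "seed": 3,
        "sim": small_sim_overrides(n_tags=100, n_individuals=50,
                                   chrom_length_cM=60.0, mean_depth=16,
                                   parent_mean_depth=24, seed=3),
        "variants": {"min_allele_individuals": 10},
        "linkage": {"min_informative": 10, "min_shared": 10,
                    "min_lod": "auto"},
    })
    return cfg, run_pipeline(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
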