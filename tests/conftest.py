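"""Shared fixtures: small seeded synthetic datasets and helper builders."""

import numpy as np
import pytest

from cobind.simulate import SyntheticConfig, generate_dataset


def small_config(seed: int = 11, n_peaks: int = 150) -> SyntheticConfig:
    cfg = SyntheticConfig(seed=seed)
    cfg.peaks.n_peaks = n_peaks
    cfg.genome.chrom_length_bp = max(400_000, n_peaks * 1500)
    cfg.dhs.n_background = 1500
    cfg.genes.n_distal_genes = 150
    cfg.genes.n_diff_genes = 60
    cfg.survival.n_patients = 120
    cfg.counts.n_specific_yap = 10
    cfg.counts.n_specific_taz = 30
    return cfg


@pytest.fixture(scope="session")
def small_dataset():
    return generate_dataset(small_config())


@pytest.fixture(scope="session")
def small_data_dir(tmp_path_factory):
    from cobind.pipeline import simulate

    d = tmp_path_factory.mktemp("data")
    simulate(11, d, small_config())
    return d


@pytest.fixture
def rng():
    return np.random.default_rng(0)
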