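import numpy as np
import pytest

from isopop import SimConfig, simulate_founders
from isopop.core import HaplotypePanel


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """Small but LD-structured panel: 5k sites on 5 Mb, 200 haplotypes."""
    return SimConfig(seed=11, n_sites=5000, chrom_length_bp=5_000_000)


@pytest.fixture(scope="session")
def small_base(small_config) -> HaplotypePanel:
    return simulate_founders(small_config)


@pytest.fixture()
def toy_panel() -> HaplotypePanel:
    """Six phased haplotypes over eight sites, hand-enumerable."""
    haps = np.array(
        [
            [1, 0, 1, 1, 0, 1, 0, 0],
            [1, 0, 1, 1, 0, 1, 0, 1],
            [0, 1, 1, 1, 1, 0, 1, 0],
            [0, 1, 0, 1, 1, 0, 1, 0],
            [1, 1, 0, 0, 1, 1, 0, 1],
            [0, 0, 1, 0, 0, 1, 1, 1],
        ],
        dtype=np.int8,
    )
    positions = np.array([100, 500, 1200, 2000, 2600, 3500, 4100, 5000])
    return HaplotypePanel(
        population_id="TOY",
        sample_ids=["T1", "T2", "T3"],
        haplotypes=haps,
        positions=positions,
        ref_alleles=["A"] * 8,
        alt_alleles=["G"] * 8,
    )


def make_panel(haps, positions=None, population_id="P") -> HaplotypePanel:
    haps = np.asarray(haps, dtype=np.int8)
    n_hap, n_sites = haps.shape
    if positions is None:
        positions = np.arange(1, n_sites + 1) * 1000
    return HaplotypePanel(
        population_id=population_id,
        sample_ids=[f"{population_id}_S{i}" for i in range(n_hap // 2)],
        haplotypes=haps,
        positions=np.asarray(positions),
        ref_alleles=["A"] * n_sites,
        alt_alleles=["C"] * n_sites,
    )
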