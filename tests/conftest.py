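import numpy as np
import pytest

from sparseselect.panel import DiploidPhasing, HaplotypePanel
from sparseselect.simdata import SweepConfig, simulate_neutral, simulate_sweep


def make_panel(alleles, spacing_bp=1000, rate_cM_per_Mb=1.0, **kw) -> HaplotypePanel:
    """Toy panel helper: integer matrix + evenly spaced positions."""
    a = np.asarray(alleles, dtype=np.uint8)
    M = a.shape[1]
    bp = (np.arange(M) + 1) * spacing_bp
    return HaplotypePanel(
        alleles=a,
        positions_bp=bp,
        positions_cM=bp * 1e-6 * rate_cM_per_Mb,
        allow_fixed=True,
        **kw,
    )


@pytest.fixture(scope="session")
def toy_identical_panel():
    """8 identical haplotypes over 6 SNPs."""
    row = np.array([1, 0, 1, 1, 0, 1], dtype=np.uint8)
    return make_panel(np.tile(row, (8, 1)))


@pytest.fixture(scope="session")
def random_panels():
    """Small random panels for oracle comparisons."""
    rng = np.random.default_rng(20140502)
    out = []
    for _ in range(25):
        H = int(rng.integers(10, 21))
        H += H % 2
        M = int(rng.integers(10, 21))
        out.append(make_panel(rng.integers(0, 2, size=(H, M))))
    return out


@pytest.fixture(scope="session")
def sweep_batch():
    """Shared sweep panels (derived allele conditioned at 0.9) — raw density."""
    return [
        simulate_sweep(SweepConfig(seed=41000 + k), chrom=f"sw{k}") for k in range(30)
    ]


@pytest.fixture(scope="session")
def neutral_batch():
    """Shared neutral panels matching the sweep batch parameters."""
    return [
        simulate_neutral(SweepConfig(seed=42000 + k), chrom=f"ne{k}")
        for k in range(30)
    ]


@pytest.fixture()
def phased_pair():
    """A small panel with known diploid pairing for switch-error tests."""
    a = np.array(
        [
            [0, 1, 0, 1, 0, 1, 0, 1],  # ind0 hap A
            [1, 0, 1, 0, 1, 0, 1, 0],  # ind0 hap B  (8 hets)
            [0, 0, 1, 1, 0, 0, 1, 1],  # ind1 hap A
            [0, 1, 1, 0, 0, 1, 1, 0],  # ind1 hap B  (4 hets)
        ],
        dtype=np.uint8,
    )
    return make_panel(a), DiploidPhasing.consecutive(4)
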