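import numpy as np
import pytest

from clipshift.annotation import GeneModel
from clipshift.pipeline import PipelineConfig, analyze_bundle
from clipshift.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def toy_gene() -> GeneModel:
    """Plus-strand two-exon coding gene, hand-checkable.

    exons [100,150) + [240,300); CDS span [120,180) -> utr5 [100,120),
    cds [120,150), utr3 [240,300), intron [150,240).
    """
    return GeneModel.from_exons(
        "toy", "chr1", "+", [(100, 150), (240, 300)], cds_span=(120, 180),
        downstream=10_000,
    )


@pytest.fixture(scope="session")
def toy_gene_minus() -> GeneModel:
    """Mirror of ``toy_gene`` on the minus strand (coordinates flipped
    around 400, so the 3'UTR lies at the lower genomic coordinates)."""
    return GeneModel.from_exons(
        "toy_minus", "chr1", "-", [(100, 160), (250, 300)],
        cds_span=(220, 280), downstream=10_000,
    )


@pytest.fixture(scope="session")
def small_bundle():
    """A 200-gene bundle for module-level checks (fast to analyze)."""
    cfg = SimulationConfig(
        seed=7, n_genes=200, n_utr3_targets=30, n_cds_targets=16,
        n_intron_targets=12,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_result(small_bundle):
    cfg = PipelineConfig(seed=7, n_perm_peaks=30, n_perm_enrichment=200)
    return analyze_bundle(small_bundle, cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
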