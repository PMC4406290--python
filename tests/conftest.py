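import numpy as np
import pandas as pd
import pytest

from mosaicscan.core_io import PipelineConfig, SampleArray
from mosaicscan.simulate import simulate_probe_map, simulate_trio_genotypes

TWO_CHROM_GENOME = {"1": 40_000_000, "2": 40_000_000}


@pytest.fixture(scope="session")
def config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def probe_map() -> pd.DataFrame:
    # ~1 probe / 4 kb over two 40 Mb chromosomes
    return simulate_probe_map(20_000, TWO_CHROM_GENOME, seed=11)


@pytest.fixture(scope="session")
def trio_genotypes(probe_map):
    return simulate_trio_genotypes(probe_map, seed=12, genome=TWO_CHROM_GENOME)


def make_sample(chrom, pos, genotype, baf, lrr=None, sample_id="S1", **kw) -> SampleArray:
    """Hand-built SampleArray from parallel value lists."""
    n = len(pos)
    probes = pd.DataFrame({
        "chrom": chrom if not isinstance(chrom, str) else [chrom] * n,
        "pos": pos,
        "genotype": genotype if not isinstance(genotype, str) else [genotype] * n,
        "baf": baf,
        "lrr": lrr if lrr is not None else np.zeros(n),
    })
    return SampleArray(sample_id=sample_id, probes=probes, **kw)


def overlaps(segments, chrom, start, end) -> bool:
    return any(
        s.chromosome == chrom and min(s.end, end) - max(s.start, start) > 0
        for s in segments
    )
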