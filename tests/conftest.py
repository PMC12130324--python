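import numpy as np
import pytest

from sescout import (
    GeneratorConfig,
    PipelineConfig,
    generate_cohorts,
    run_pipeline,
)


def random_intervals(rng, n, chroms=("chr1", "chr2"), span=100_000, max_len=2_000):
    """n random intervals for oracle comparisons."""
    from sescout.core import GenomicInterval

    out = []
    for _ in range(n):
        chrom = str(rng.choice(chroms))
        start = int(rng.integers(0, span))
        length = int(rng.integers(1, max_len))
        out.append(GenomicInterval(chrom, start, start + length))
    return out


@pytest.fixture(scope="session")
def bundle1(tmp_path_factory):
    """Default synthetic bundle at seed 1, shared across the session."""
    outdir = tmp_path_factory.mktemp("bundle1")
    bundle, truth = generate_cohorts(GeneratorConfig(seed=1), outdir)
    return bundle, truth


@pytest.fixture(scope="session")
def pipeline1(bundle1, tmp_path_factory):
    """Full pipeline run on the seed-1 bundle."""
    bundle, truth = bundle1
    outdir = tmp_path_factory.mktemp("pipe1")
    result = run_pipeline(PipelineConfig.from_bundle(bundle, outdir))
    return result, truth
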