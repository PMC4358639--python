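import random

import pytest

import seedex as sx
from seedex.gapped import GappedConfig
from seedex.nongapped import NongappedConfig
from seedex.pipeline import PipelineConfig, run
from seedex.simeval import simulate_reads, simulate_reference


def random_dna(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))


@pytest.fixture(scope="session")
def reference_50k():
    name, seq = simulate_reference(50000, seed=11)
    return [(name, seq)]


@pytest.fixture(scope="session")
def index_50k(reference_50k):
    return sx.build_index(reference_50k)


@pytest.fixture(scope="session")
def pipeline_cfg(index_50k):
    return PipelineConfig(
        nongapped=NongappedConfig(seed=index_50k.nongapped.seed),
        gapped=GappedConfig(seed=index_50k.gapped.seed),
    )


@pytest.fixture(scope="session")
def benchmark_run(tmp_path_factory, reference_50k, index_50k, pipeline_cfg):
    """Fixed-seed paired-end benchmark: 300 pairs at 1% substitutions and
    0.1% indels from the repeat-free 50 kb reference."""
    out = tmp_path_factory.mktemp("bench") / "out.sam"
    r1, r2, truth = simulate_reads(reference_50k, 300, read_len=100,
                                   sub_rate=0.01, indel_rate=0.001, seed=12)
    counters = run(reference_50k, index_50k, r1, out, pipeline_cfg, reads2=r2)
    return {"sam": out, "truth": truth, "counters": counters,
            "reads1": r1, "reads2": r2}
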