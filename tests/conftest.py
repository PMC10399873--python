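import numpy as np
import pytest

from cnvprior.benchmark import run_benchmark
from cnvprior.io import CNVRecord, Cohort, GeneRecord, build_cohort


@pytest.fixture(scope="session")
def benchmark_runs():
    """Five independent training runs on the reference planted-gene cohort."""
    return [run_benchmark(seed) for seed in (1, 2, 3, 4, 5)]


@pytest.fixture
def tiny_genes():
    return [
        GeneRecord("GA", "GA", "1", 10_000, 20_000, "coding"),
        GeneRecord("GB", "GB", "1", 40_000, 50_000, "lncRNA"),
        GeneRecord("GC", "GC", "2", 10_000, 20_000, "coding"),
    ]


@pytest.fixture
def tiny_cohort():
    """4 cases / 4 controls; cases 1-3 and control 2 carry a deletion over GA."""
    records = []
    for i in (1, 2, 3):
        records.append(CNVRecord(f"case{i}", "1", 12_000, 30_000, "del", "case"))
    records.append(CNVRecord("ctrl2", "1", 5_000, 15_000, "del", "control"))
    # background dups elsewhere so every sample has a record; the chrom-2
    # dups overlap GC in controls only
    records.append(CNVRecord("case4", "1", 60_000, 70_000, "dup", "case"))
    for i in (1, 3, 4):
        records.append(CNVRecord(f"ctrl{i}", "2", 15_000, 45_000, "dup", "control"))
    return build_cohort(records, disease_tag="tiny")
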