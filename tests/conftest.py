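import pandas as pd
import pytest

from pumiclip import SynthConfig, simulate_experiment
from pumiclip.core import GenomicInterval, ReadRecord


def make_read(chrom, start, end, strand="+", umi="ACGTACGTAC", sample="s1"):
    return ReadRecord(GenomicInterval(chrom, start, end, strand), sample, umi)


@pytest.fixture(scope="session")
def default_experiment():
    """One deduplicated default-size synthetic experiment, shared read-only."""
    exp = simulate_experiment(SynthConfig(seed=0))
    for lib in exp.libraries:
        lib.dedup()
    return exp


@pytest.fixture(scope="session")
def super_experiment():
    """Experiment with the synthetic Norad super-target enabled."""
    exp = simulate_experiment(
        SynthConfig(seed=0, super_target=True,
                    reads_per_ip_sample=50000, reads_per_input_sample=50000)
    )
    for lib in exp.libraries:
        lib.dedup()
    return exp


@pytest.fixture()
def toy_matrix():
    counts = pd.DataFrame(
        {
            "WT_rna_rep1": [100, 0, 3, 50],
            "WT_rna_rep2": [120, 0, 0, 60],
            "KO_rna_rep1": [80, 0, 1, 55],
            "KO_rna_rep2": [82, 0, 0, 45],
        },
        index=["g1", "g2", "g3", "g4"],
    )
    samples = pd.DataFrame(
        {
            "sample_id": counts.columns,
            "genotype": ["WT", "WT", "KO", "KO"],
            "replicate": [1, 2, 1, 2],
        }
    )
    from pumiclip.expression import ExpressionMatrix

    return ExpressionMatrix(counts, samples,
                            pd.Series({"g1": 1000, "g2": 500, "g3": 2000, "g4": 1000}))
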