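import pandas as pd
import pytest

from gistflow.pipeline import RunConfig, run_all
from gistflow.simulate import SimConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort(tmp_path_factory):
    """Default synthetic cohort: 14 patients / 19 samples, 60x, 0.5 somatic/Mb."""
    out = tmp_path_factory.mktemp("cohort")
    path, truth = generate_cohort(SimConfig(seed=11), out / "c")
    return path, truth


@pytest.fixture(scope="session")
def default_run(default_cohort, tmp_path_factory):
    """Full pipeline run over the default cohort."""
    cohort, truth = default_cohort
    out = tmp_path_factory.mktemp("run") / "r"
    report = run_all(RunConfig(cohort_dir=str(cohort), out_dir=str(out)))
    return report, out


@pytest.fixture
def toy_gene_model():
    """Six genes on two chromosomes for fusion-triage unit tests.

    chr1 '+' order: GA (1k-5k), GB (60k-80k, 55 kb gap), GC (2.3M-2.4M);
    chr1 '-': GD (100k-120k); chr2: GE '+' , GF '-'.
    """
    return pd.DataFrame(
        [
            {"chrom": "chr1", "start": 1_000, "end": 5_000, "name": "GA", "score": 0, "strand": "+"},
            {"chrom": "chr1", "start": 60_000, "end": 80_000, "name": "GB", "score": 0, "strand": "+"},
            {"chrom": "chr1", "start": 2_300_000, "end": 2_400_000, "name": "GC", "score": 0, "strand": "+"},
            {"chrom": "chr1", "start": 100_000, "end": 120_000, "name": "GD", "score": 0, "strand": "-"},
            {"chrom": "chr2", "start": 10_000, "end": 20_000, "name": "GE", "score": 0, "strand": "+"},
            {"chrom": "chr2", "start": 500_000, "end": 600_000, "name": "GF", "score": 0, "strand": "-"},
        ]
    )
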