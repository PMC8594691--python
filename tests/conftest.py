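import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from epiewas.containers import MethylationMatrix, RegionSet, SampleFrame
from epiewas.simulate import make_worked_example

settings.register_profile("reproducible", derandomize=True)
settings.load_profile("reproducible")


@pytest.fixture(scope="session")
def worked_example(tmp_path_factory):
    """The committed tiny bundle: 4 samples, 10 CpGs, 3 SNPs, 2 DMR sets."""
    outdir = tmp_path_factory.mktemp("worked_example")
    return make_worked_example(outdir)


@pytest.fixture
def simple_samples():
    return SampleFrame(
        sample_ids=["S1", "S2", "S3", "S4"],
        env=np.array([1.0, 2.0, 3.0, 4.0]),
    )


def make_matrix(values, starts=None, chrom="chr1", samples=None, context="CpG"):
    values = np.asarray(values, dtype=float)
    n_pos, n_samp = values.shape
    if starts is None:
        starts = np.arange(n_pos) * 10 + 10
    if samples is None:
        samples = [f"S{j + 1}" for j in range(n_samp)]
    positions = pd.DataFrame({
        "chrom": chrom, "start": starts, "end": np.asarray(starts) + 1,
        "context": context,
    })
    return MethylationMatrix(positions=positions, samples=samples, values=values)


def make_regions(rows, merged=False):
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "label"])
    return RegionSet(intervals=df, merged_flag=merged)
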