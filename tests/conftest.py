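import numpy as np
import pandas as pd
import pytest

from cogsvd.data_io import CopyNumberDataset


def make_probes(genome: dict[str, int], spacing: int = 1000, length: int = 25,
                with_arms: bool = True) -> pd.DataFrame:
    """Evenly spaced toy annotation; arms split at the chromosome midpoint."""
    rows = []
    for chrom, count in genome.items():
        for i in range(count):
            rows.append(
                {
                    "probe_id": f"{chrom}_p{i:04d}",
                    "chromosome": chrom,
                    "start": i * spacing,
                    "end": i * spacing + length,
                    "arm": "p" if i < count // 2 else "q",
                }
            )
    frame = pd.DataFrame(rows)
    if not with_arms:
        frame = frame.drop(columns="arm")
    return frame


def make_dataset(values, genome=None, patients=None) -> CopyNumberDataset:
    values = np.asarray(values, dtype=float)
    if genome is None:
        genome = {"chr1": values.shape[0]}
    probes = make_probes(genome)
    if patients is None:
        patients = [f"pt{j}" for j in range(values.shape[1])]
    return CopyNumberDataset(values, probes, patients)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def random_pair(rng):
    d1 = rng.standard_normal((40, 5))
    d2 = rng.standard_normal((30, 5))
    return d1, d2
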