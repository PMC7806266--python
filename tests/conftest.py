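import numpy as np
import pytest

from replicheck import (CopyProfile, GenomeSpec, Origin, default_genome,
                        default_origins)


@pytest.fixture(scope="session")
def world():
    """The packaged stated world: toy genome + 121-origin registry."""
    genome = default_genome()
    return genome, default_origins(genome)


@pytest.fixture
def toy_genome():
    return GenomeSpec((("chr1", 50_000),))


@pytest.fixture
def toy_origin():
    return Origin(chrom="chr1", pos=25_000, name="ori1", trep=20.0, fire_sd=0.0)


def make_profile(values_by_chrom, bin_width=1000, baseline=None, masked=None):
    """Build a CopyProfile from raw per-chromosome value arrays."""
    chroms = tuple(
        (c, len(v) * bin_width) for c, v in values_by_chrom.items()
    )
    genome = GenomeSpec(chroms)
    values = {c: np.asarray(v, dtype=float) for c, v in values_by_chrom.items()}
    if masked is None:
        masked = {c: np.zeros(len(v), dtype=bool) for c, v in values.items()}
    return CopyProfile(genome, bin_width, values, masked, baseline=baseline)
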