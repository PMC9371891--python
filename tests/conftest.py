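import numpy as np
import pytest

import cenlandscape as cl
from cenlandscape.annotations import CentromereModel, GenomicInterval
from cenlandscape.ingest import TranscriptAlignment


@pytest.fixture(scope="session")
def small_cfg():
    return cl.SimulationConfig(n_chromosomes=3, seed=11, duplicate_rate=0.0,
                               n_background_reads=60)


@pytest.fixture(scope="session")
def small_genome(small_cfg):
    return cl.build_genome(small_cfg)


@pytest.fixture
def make_cen():
    """Factory for a toy centromere with controllable geometry."""

    def _make(chrom="chrT", start=1000, orientation="+",
              lens=(8, 84, 25), cen_id="CENT"):
        l1, l2, l3 = lens
        a, b, c, d = start, start + l1, start + l1 + l2, start + l1 + l2 + l3
        if orientation == "+":
            cdeI = GenomicInterval(chrom, a, b)
            cdeII = GenomicInterval(chrom, b, c)
            cdeIII = GenomicInterval(chrom, c, d)
        else:
            a, b, c2 = start, start + l3, start + l3 + l2
            cdeIII = GenomicInterval(chrom, a, b)
            cdeII = GenomicInterval(chrom, b, c2)
            cdeI = GenomicInterval(chrom, c2, c2 + l1)
        return CentromereModel(cen_id, chrom, cdeI, cdeII, cdeIII, orientation)

    return _make


@pytest.fixture
def make_read():
    """Factory for a single-block read with explicit strand and footprint."""

    counter = {"n": 0}

    def _make(start, end, strand="+", chrom="chrT", umi="ACGTAC",
              read_id=None, blocks=None):
        if read_id is None:
            read_id = f"t{counter['n']:05d}"
            counter["n"] += 1
        if blocks is None:
            blocks = ((start, end),)
        return TranscriptAlignment(read_id, umi, chrom, strand, tuple(blocks))

    return _make
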