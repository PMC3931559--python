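import numpy as np
import pytest

import rdna_chromatin as rc


@pytest.fixture
def small_build():
    """4-kb repeat prepended to a 12-kb host with one pseudogene."""
    build, truth = rc.simulate_genome(
        rc.SyntheticGenomeSpec(
            host_length=12_000,
            repeat_length=4_000,
            n_pseudogenes=1,
            pseudogene_fraction=0.1,
            seed=42,
        )
    )
    return build, truth


@pytest.fixture
def clean_build():
    """2.5-kb fully unique repeat on an 8-kb host, no pseudogenes."""
    build, _ = rc.simulate_genome(
        rc.SyntheticGenomeSpec(
            host_length=8_000, repeat_length=2_500, n_pseudogenes=0, seed=7
        )
    )
    return build


def region_of(build):
    ins = build.insertion
    return ins.chrom, 0, len(build.sequences[ins.chrom])
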