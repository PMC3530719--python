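import numpy as np
import pandas as pd
import pytest

from bedmr.core import GenomeSpec, SegmentedProfile
from bedmr.simulate import SimConfig


def make_profile(sample_id, chrom_segments):
    """chrom_segments: {chrom: [(start, end, ratio), ...]}"""
    rows = [
        (chrom, s, e, r)
        for chrom, segs in chrom_segments.items()
        for (s, e, r) in segs
    ]
    return SegmentedProfile(
        sample_id, pd.DataFrame(rows, columns=["chrom", "start", "end", "ratio"])
    )


@pytest.fixture
def small_genome():
    return GenomeSpec(("chr1", "chr2"), (10_000_000, 8_000_000))


@pytest.fixture
def tiny_genome():
    return GenomeSpec(("chr1",), (200,))


@pytest.fixture(scope="session")
def sim_config():
    """Small but realistic simulation settings shared by recovery tests."""
    return SimConfig(
        n_samples=50,
        n_normals=5,
        n_chroms=2,
        chrom_length=30_000_000,
        background_bp_rate=0.5,
        n_hotspots=2,
        hotspot_sd=200_000.0,
        hotspot_weight=0.7,
        seed=11,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
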