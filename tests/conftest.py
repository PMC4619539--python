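import numpy as np
import pytest

from mcrkit.io import GenomicInterval
from mcrkit.synthetic import CohortSpec, PlantedHotspot, simulate_cohort

PLANTED = GenomicInterval("chr1", 2_000_000, 2_300_000)


@pytest.fixture(scope="session")
def small_cohort():
    """10-sample cohort with one planted hotspot on a 10 Mb chromosome."""
    spec = CohortSpec(
        n_samples=10,
        chrom_lengths={"chr1": 10_000_000},
        planted_hotspots=[PlantedHotspot(PLANTED, 0.5, 0.2)],
        passenger_rate=1.0,
        probe_spacing=50_000,
        seed=7,
    )
    segments, clinical, truth = simulate_cohort(spec)
    return spec, segments, clinical, truth


def random_amplicon_map(rng, n_samples=10, chrom_length=100_000, max_intervals=5):
    """Random per-sample amplified intervals on a toy chromosome."""
    amplicons = {}
    for i in range(n_samples):
        n_iv = int(rng.integers(0, max_intervals + 1))
        ivs = []
        for _ in range(n_iv):
            a = int(rng.integers(1, chrom_length))
            b = int(rng.integers(a, min(chrom_length, a + chrom_length // 4) + 1))
            ivs.append(GenomicInterval("chr1", a, b))
        amplicons[f"S{i}"] = ivs
    return amplicons
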