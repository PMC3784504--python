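from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from chiptile import (
    GenomeModel,
    NoiseModel,
    ProbeTable,
    Sample,
    ScoreTrack,
    plant_sites,
    simulate_probe_intensities,
)


@pytest.fixture
def small_genome() -> GenomeModel:
    """Two 300 kb chromosomes — big enough for well-separated sites."""
    return GenomeModel(("chrA", "chrB"), (300_000, 300_000))


@pytest.fixture
def tiny_table() -> ProbeTable:
    """Three probes, one replicate of each channel, hand-writable numbers."""
    frame = pd.DataFrame(
        {
            "chrom": ["chr1", "chr1", "chr1"],
            "start": [0, 35, 70],
            "end": [25, 60, 95],
            "ChIP_rep1": [8.0, 16.0, 4.0],
            "Mock_rep1": [2.0, 4.0, 4.0],
            "Input_rep1": [2.0, 4.0, 4.0],
        }
    )
    samples = [
        Sample("ChIP_rep1", "ChIP", 1),
        Sample("Mock_rep1", "Mock", 1),
        Sample("Input_rep1", "Input", 1),
    ]
    return ProbeTable(frame, samples)


@pytest.fixture
def simulated_dataset(small_genome):
    """A small planted dataset with strong signal, shared across tests."""
    factor = plant_sites(
        small_genome, 20, effect_size=3.0, rng_seed=11, factor_name="smc1"
    )
    table, truth = simulate_probe_intensities(
        small_genome, factor, NoiseModel(probe_noise_sd=0.5), n_replicates=2,
        rng_seed=12,
    )
    return table, truth


def make_track(scores, chrom="chr1", step=35, probe_length=25) -> ScoreTrack:
    """A ScoreTrack on a regular grid from a plain list of scores."""
    scores = np.asarray(scores, dtype=float)
    if isinstance(chrom, str):
        chroms = [chrom] * len(scores)
    else:
        chroms = list(chrom)
    starts = []
    counters: dict[str, int] = {}
    for c in chroms:
        i = counters.get(c, 0)
        starts.append(i * step)
        counters[c] = i + 1
    frame = pd.DataFrame(
        {
            "chrom": chroms,
            "start": starts,
            "end": [s + probe_length for s in starts],
        }
    )
    return ScoreTrack(probes=frame, score=scores)


@pytest.fixture
def track_factory():
    return make_track
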