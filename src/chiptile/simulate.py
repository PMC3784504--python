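"""Synthetic tiling-array data with planted binding sites and ground truth.

The generator emulates the structure of a two-colour-free tiling ChIP
experiment on a short-probe array: a genome tiled at ~35 bp resolution with
25 bp probes, ChIP / Mock / Input channels, two biological replicates per
antibody, and binding sites of roughly sonication-fragment width (~500 bp).

Signal model, all in log2 intensity units:

* Input   = 2 ** (baseline + probe_noise)
* ChIP    = 2 ** (baseline + site_effect + probe_noise + replicate_shift)
* Mock    = ChIP formula with the site effect scaled by ``mock_effect_fraction``

where ``site_effect`` applies to a probe exactly when the probe midpoint
falls inside a planted site. Probe noise is drawn independently per probe and
per hybridised sample; the replicate shift is a single normal draw per
(channel, replicate), mimicking between-array level differences. Everything
is deterministic given the configuration and a seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, PlacementError
from .io import IntervalRecord, ProbeTable, Sample

DEFAULT_CHROM_NAMES = ("chr2L", "chr2R", "chr3L", "chr3R")
DEFAULT_CHROM_LENGTH = 1_000_000


@dataclass(frozen=True)
class GenomeModel:
    """Tiled-genome geometry: chromosome sizes and the probe layout.

    Defaults: 25 bp probes every 35 bp (the ~35 bp resolution of short-probe
    genomic tiling arrays) on four 1 Mb chromosomes, a desk-scale stand-in
    for the fly chromosome arms.
    """

    chrom_names: tuple[str, ...] = DEFAULT_CHROM_NAMES
    chrom_lengths: tuple[int, ...] = (DEFAULT_CHROM_LENGTH,) * 4
    probe_length: int = 25
    probe_step: int = 35

    def __post_init__(self) -> None:
        if len(self.chrom_names) != len(self.chrom_lengths):
            raise ConfigurationError("chrom_names and chrom_lengths differ in length")
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ConfigurationError("duplicate chromosome names")
        if any(length <= 0 for length in self.chrom_lengths):
            raise ConfigurationError("chromosome lengths must be > 0")
        if self.probe_length <= 0:
            raise ConfigurationError("probe_length must be > 0")
        if self.probe_step < 1:
            raise ConfigurationError("probe_step must be >= 1")

    @property
    def sizes(self) -> dict[str, int]:
        return dict(zip(self.chrom_names, self.chrom_lengths))

    def n_probes(self, chrom: str) -> int:
        length = self.sizes[chrom]
        if length < self.probe_length:
            return 0
        return (length - self.probe_length) // self.probe_step + 1


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise parameters, all in log2 intensity units.

    baseline_log_intensity
        Mean log2 raw intensity of an unbound probe (10 ~ intensities near
        1024, typical of scanned short-probe arrays).
    probe_noise_sd
        Per-probe, per-sample lognormal noise (normal in log2 space).
    replicate_shift_sd
        SD of the per-(channel, replicate) level shift.
    mock_effect_fraction
        Fraction of the site effect leaking into the Mock channel; a small
        positive default keeps the mock-subtraction step non-trivial.
    """

    baseline_log_intensity: float = 10.0
    probe_noise_sd: float = 0.5
    replicate_shift_sd: float = 0.1
    mock_effect_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.probe_noise_sd < 0 or self.replicate_shift_sd < 0:
            raise ConfigurationError("noise standard deviations must be >= 0")
        if not 0.0 <= self.mock_effect_fraction <= 1.0:
            raise ConfigurationError("mock_effect_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class FactorModel:
    """Planted binding sites (0-based half-open) and log2 effects for one factor."""

    factor_name: str
    site_intervals: tuple[tuple[str, int, int], ...]
    effect_sizes: tuple[float, ...]
    shared_indices: tuple[int, ...] = ()  # positions copied from another factor

    def __post_init__(self) -> None:
        if len(self.site_intervals) != len(self.effect_sizes):
            raise ConfigurationError("one effect size per site required")
        for chrom, start, end in self.site_intervals:
            if start < 0 or end <= start:
                raise ConfigurationError(f"bad site ({chrom}, {start}, {end})")
        if any(e < 0 for e in self.effect_sizes):
            raise ConfigurationError("effect sizes must be >= 0")

    def __len__(self) -> int:
        return len(self.site_intervals)

    def to_records(self) -> list[IntervalRecord]:
        """Truth sites as BED-style records; score = effect x 100, rounded."""
        return [
            IntervalRecord(c, s, e, self.factor_name, round(eff * 100))
            for (c, s, e), eff in zip(self.site_intervals, self.effect_sizes)
        ]


@dataclass(frozen=True)
class SimulationTruth:
    """Everything needed to check recovery: the planted factor, genome and seed."""

    genome: GenomeModel
    factor: FactorModel
    noise: NoiseModel
    n_replicates: int
    seed: int


def build_genome(genome: GenomeModel) -> ProbeTable:
    """Lay out the probe grid: ascending, per-chromosome, 0-based half-open."""
    chroms: list[str] = []
    starts: list[np.ndarray] = []
    for name in genome.chrom_names:
        n = genome.n_probes(name)
        s = np.arange(n, dtype=np.int64) * genome.probe_step
        starts.append(s)
        chroms.extend([name] * n)
    start = np.concatenate(starts) if starts else np.empty(0, dtype=np.int64)
    frame = pd.DataFrame(
        {"chrom": chroms, "start": start, "end": start + genome.probe_length}
    )
    return ProbeTable(frame, samples=())


def _draw_width(rng: np.random.Generator, mean: float, sd: float, minimum: float) -> int:
    # truncated normal by redraw; sonication sets ~500 bp fragments
    for _ in range(1000):
        w = rng.normal(mean, sd)
        if w >= minimum:
            return int(round(w))
    raise PlacementError("could not draw a site width above the minimum")


def plant_sites(
    genome: GenomeModel,
    n_sites: int,
    width_mean: float = 500.0,
    width_sd: float = 100.0,
    min_width: float = 200.0,
    effect_size: float = 2.0,
    shared_with: FactorModel | None = None,
    shared_fraction: float = 0.0,
    rng_seed: int = 0,
    factor_name: str = "factor",
    max_tries: int = 1000,
) -> FactorModel:
    """Place ``n_sites`` binding sites, optionally sharing positions with
    another factor.

    ``round(shared_fraction * n_sites)`` sites are copied verbatim from
    ``shared_with`` (its first sites, in order); the remainder are placed
    uniformly on the genome, never overlapping another site of this factor.
    Deterministic given the seed.
    """
    if n_sites < 0:
        raise ConfigurationError("n_sites must be >= 0")
    if not 0.0 <= shared_fraction <= 1.0:
        raise ConfigurationError("shared_fraction must lie in [0, 1]")
    rng = np.random.default_rng(rng_seed)
    sizes = genome.sizes

    sites: list[tuple[str, int, int]] = []
    shared_idx: list[int] = []
    if shared_with is not None and shared_fraction > 0:
        n_shared = round(shared_fraction * n_sites)
        if n_shared > len(shared_with):
            raise ConfigurationError(
                f"{shared_with.factor_name} has only {len(shared_with)} sites, "
                f"cannot share {n_shared}"
            )
        sites.extend(shared_with.site_intervals[:n_shared])
        shared_idx = list(range(n_shared))

    chrom_names = list(sizes)
    weights = np.array([sizes[c] for c in chrom_names], dtype=float)
    weights /= weights.sum()

    while len(sites) < n_sites:
        placed = False
        for _ in range(max_tries):
            chrom = chrom_names[rng.choice(len(chrom_names), p=weights)]
            width = _draw_width(rng, width_mean, width_sd, min_width)
            length = sizes[chrom]
            if width > length:
                continue
            start = int(rng.integers(0, length - width + 1))
            end = start + width
            clash = any(
                c == chrom and start < e and end > s for c, s, e in sites
            )
            if not clash:
                sites.append((chrom, start, end))
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"could not place site {len(sites) + 1}/{n_sites} without overlap "
                f"after {max_tries} tries"
            )

    return FactorModel(
        factor_name=factor_name,
        site_intervals=tuple(sites),
        effect_sizes=(float(effect_size),) * len(sites),
        shared_indices=tuple(shared_idx),
    )


def _site_effects_per_probe(table: ProbeTable, factor: FactorModel) -> np.ndarray:
    mids = table.midpoints()
    chrom = table.frame["chrom"].to_numpy()
    effect = np.zeros(len(table))
    for (c, s, e), eff in zip(factor.site_intervals, factor.effect_sizes):
        mask = (chrom == c) & (mids >= s) & (mids < e)
        effect[mask] = eff
    return effect


def simulate_probe_intensities(
    genome: GenomeModel,
    factor: FactorModel,
    noise: NoiseModel = NoiseModel(),
    n_replicates: int = 2,
    rng_seed: int = 0,
) -> tuple[ProbeTable, SimulationTruth]:
    """Simulate raw ChIP/Mock/Input intensities for one factor.

    Draw order is fixed (per replicate: Input noise, ChIP noise, ChIP shift,
    Mock noise, Mock shift) so the same (config, seed) reproduces the table
    exactly.
    """
    if n_replicates < 1:
        raise ConfigurationError("n_replicates must be >= 1")
    skeleton = build_genome(genome)
    n = len(skeleton)
    effect = _site_effects_per_probe(skeleton, factor)
    rng = np.random.default_rng(rng_seed)

    columns: dict[str, np.ndarray] = {}
    samples: list[Sample] = []
    base = noise.baseline_log_intensity
    for rep in range(1, n_replicates + 1):
        input_noise = rng.normal(0.0, noise.probe_noise_sd, n)
        chip_noise = rng.normal(0.0, noise.probe_noise_sd, n)
        chip_shift = rng.normal(0.0, noise.replicate_shift_sd)
        mock_noise = rng.normal(0.0, noise.probe_noise_sd, n)
        mock_shift = rng.normal(0.0, noise.replicate_shift_sd)
        columns[f"Input_rep{rep}"] = np.exp2(base + input_noise)
        columns[f"ChIP_rep{rep}"] = np.exp2(base + effect + chip_noise + chip_shift)
        columns[f"Mock_rep{rep}"] = np.exp2(
            base + noise.mock_effect_fraction * effect + mock_noise + mock_shift
        )

    for channel in ("ChIP", "Mock", "Input"):
        for rep in range(1, n_replicates + 1):
            samples.append(Sample(f"{channel}_rep{rep}", channel, rep))
    frame = skeleton.frame.copy()
    for s in samples:
        frame[s.name] = columns[s.name]
    table = ProbeTable(frame, samples, validate=False)
    truth = SimulationTruth(
        genome=genome,
        factor=factor,
        noise=noise,
        n_replicates=n_replicates,
        seed=rng_seed,
    )
    return table, truth
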