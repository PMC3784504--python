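"""Probe-level ChIP-chip enrichment scores.

The score pipeline, per factor:

1. log2((ChIP + c) / (Input + c)) and log2((Mock + c) / (Input + c)) per
   replicate, with pseudocount ``c`` guarding zero intensities;
2. quantile normalization of all ratio columns (ChIP and Mock replicates
   together, "in parallel") to a common empirical distribution;
3. unweighted mean across replicates, per channel;
4. median scaling: subtraction of the genome-wide median, setting the null
   level of each averaged log-ratio to 0;
5. score = scaled ChIP ratio minus scaled Mock ratio, per probe.

Quantile normalization maps each column's ranks onto the reference
distribution (the row-wise mean of the per-column sorted vectors); tied
values within a column receive the mean of the reference values across the
tied span, so identical inputs always map to identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, GridMismatchError
from .io import ProbeTable, ScoreTrack


@dataclass
class RatioMatrix:
    """Per-probe log2(channel/Input) ratios; one column per (channel, replicate)."""

    probes: pd.DataFrame
    values: np.ndarray  # shape (n_probes, n_columns)
    columns: tuple[tuple[str, int], ...]  # (channel, replicate) per column

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ConfigurationError("ratio matrix must be 2-D")
        if self.values.shape[0] != len(self.probes):
            raise GridMismatchError("ratio rows do not match the probe grid")
        if self.values.shape[1] != len(self.columns):
            raise ConfigurationError("one (channel, replicate) label per column required")
        if not np.all(np.isfinite(self.values)):
            raise ConfigurationError("ratio matrix contains non-finite values")

    def channel_columns(self, channel: str) -> np.ndarray:
        idx = [i for i, (ch, _) in enumerate(self.columns) if ch == channel]
        if not idx:
            raise ConfigurationError(f"channel {channel!r} absent from ratio matrix")
        return self.values[:, idx]


def compute_log_ratios(
    table: ProbeTable,
    pseudocount: float = 1.0,
    channels: tuple[str, ...] = ("ChIP", "Mock"),
) -> RatioMatrix:
    """log2((channel + c) / (Input + c)) per probe, per replicate.

    Each replicate's channel intensities are divided by the same replicate's
    Input; a missing Input replicate is a configuration error.
    """
    if pseudocount < 0:
        raise ConfigurationError("pseudocount must be >= 0")
    cols: list[np.ndarray] = []
    labels: list[tuple[str, int]] = []
    for channel in channels:
        for s in table.samples_for(channel):
            inp = table.sample("Input", s.replicate)  # raises if absent
            num = table.intensity(s) + pseudocount
            den = table.intensity(inp) + pseudocount
            if np.any(num <= 0) or np.any(den <= 0):
                raise ConfigurationError(
                    "non-positive intensity after pseudocount; increase pseudocount"
                )
            cols.append(np.log2(num / den))
            labels.append((channel, s.replicate))
    if not cols:
        raise ConfigurationError(f"no samples found for channels {channels}")
    return RatioMatrix(
        probes=table.probes.copy(),
        values=np.column_stack(cols),
        columns=tuple(labels),
    )


def _quantile_normalize_values(values: np.ndarray) -> np.ndarray:
    n, m = values.shape
    if n == 0:
        return values.copy()
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values, dtype=float)
    for j in range(m):
        col = values[:, j]
        order = np.argsort(col, kind="stable")
        sorted_vals = col[order]
        mapped = np.empty(n)
        i = 0
        while i < n:
            k = i
            while k + 1 < n and sorted_vals[k + 1] == sorted_vals[i]:
                k += 1
            mapped[i : k + 1] = reference[i : k + 1].mean()
            i = k + 1
        out[order, j] = mapped
    return out


def quantile_normalize(matrix: RatioMatrix) -> RatioMatrix:
    """Force every column onto the common reference distribution.

    The reference is the row-wise mean of the per-column sorted vectors; rank
    order within each column is preserved, and ties receive the mean of the
    reference values over the tied span.
    """
    return RatioMatrix(
        probes=matrix.probes,
        values=_quantile_normalize_values(matrix.values),
        columns=matrix.columns,
    )


def average_replicates(matrix: RatioMatrix, channel: str) -> np.ndarray:
    """Unweighted mean of a channel's replicate ratio columns, per probe."""
    return matrix.channel_columns(channel).mean(axis=1)


def median_scale(vector: np.ndarray) -> np.ndarray:
    """Centre a log-ratio vector by subtracting its genome-wide median."""
    vector = np.asarray(vector, dtype=float)
    if vector.size == 0:
        raise ConfigurationError("cannot median-scale an empty vector")
    return vector - np.median(vector)


def compute_score(chip: ScoreTrack, mock: ScoreTrack) -> ScoreTrack:
    """ChIP-chip score: scaled ChIP ratio minus the matching Mock ratio."""
    if not chip.same_grid(mock):
        raise GridMismatchError("ChIP and Mock components are on different probe grids")
    provenance = dict(chip.provenance)
    provenance.update({f"mock_{k}": v for k, v in mock.provenance.items()})
    return ScoreTrack(
        probes=chip.probes,
        score=chip.score - mock.score,
        provenance=provenance,
    )


def score_probe_table(
    table: ProbeTable,
    factor_name: str = "",
    pseudocount: float = 1.0,
) -> ScoreTrack:
    """Run the full scoring pipeline on a raw probe table.

    Requires ChIP, Mock and Input channels with matching replicate indices.
    Provenance records the pseudocount and the medians subtracted from the
    averaged ChIP and Mock ratios.
    """
    ratios = compute_log_ratios(table, pseudocount=pseudocount)
    normalized = quantile_normalize(ratios)
    chip_avg = average_replicates(normalized, "ChIP")
    mock_avg = average_replicates(normalized, "Mock")
    chip_median = float(np.median(chip_avg))
    mock_median = float(np.median(mock_avg))
    score = median_scale(chip_avg) - median_scale(mock_avg)
    n_reps = sum(1 for ch, _ in ratios.columns if ch == "ChIP")
    return ScoreTrack(
        probes=table.probes.copy(),
        score=score,
        provenance={
            "factor": factor_name,
            "pseudocount": pseudocount,
            "chip_median": chip_median,
            "mock_median": mock_median,
            "n_replicates": n_reps,
        },
    )


def replicate_ratio_tracks(
    table: ProbeTable,
    channel: str = "ChIP",
    pseudocount: float = 1.0,
) -> list[ScoreTrack]:
    """Per-replicate normalized log-ratio tracks, for replicate agreement checks."""
    ratios = quantile_normalize(compute_log_ratios(table, pseudocount=pseudocount))
    tracks = []
    for i, (ch, rep) in enumerate(ratios.columns):
        if ch != channel:
            continue
        tracks.append(
            ScoreTrack(
                probes=table.probes.copy(),
                score=ratios.values[:, i],
                provenance={"channel": ch, "replicate": rep},
            )
        )
    return tracks
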