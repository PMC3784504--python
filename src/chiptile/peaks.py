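"""Permutation-FDR peak calling on probe-level score tracks.

Peaks are maximal runs of probes scoring at or above a threshold ``t``,
allowing up to ``max_gap`` consecutive sub-threshold probes inside a run and
never bridging chromosomes; a run qualifies when it contains at least
``min_probes`` supra-threshold probes, and the peak spans the first to the
last supra-threshold probe (extended to probe boundaries).

The threshold is chosen by a permutation FDR: probe scores are shuffled
uniformly within each chromosome (destroying spatial clustering while
preserving each chromosome's score distribution), peaks are re-counted on
each of ``n_permutations`` shuffled tracks over a grid of candidate
thresholds, and FDR(t) = min(1, mean null peak count / max(1, observed peak
count)), made monotone non-increasing in t by a running minimum. The
reported loci are the peaks at the smallest grid threshold whose adjusted
FDR falls below ``alpha``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .coloc import LocusSet
from .errors import ConfigurationError
from .io import ScoreTrack

DEFAULT_THRESHOLD_QUANTILES: tuple[float, ...] = tuple(
    round(q, 3) for q in np.arange(0.90, 0.999, 0.01)
) + (0.995, 0.999)


@dataclass(frozen=True)
class PeakCallParams:
    """Tunable parameters of the permutation-FDR peak caller.

    Defaults assume ~500 bp binding footprints on a 35 bp grid: a peak needs
    at least 4 supra-threshold probes (~140 bp) and may contain single-probe
    dropouts (max_gap=1). Candidate thresholds are score quantiles.
    Permutation ``r`` uses seed ``seed + r``.
    """

    min_probes: int = 4
    max_gap: int = 1
    n_permutations: int = 100
    alpha: float = 0.01
    threshold_quantiles: tuple[float, ...] = DEFAULT_THRESHOLD_QUANTILES
    thresholds: tuple[float, ...] | None = None  # explicit grid overrides quantiles
    seed: int = 0
    per_chromosome: bool = True  # shuffle within chromosomes vs genome-wide

    def __post_init__(self) -> None:
        if self.min_probes < 1:
            raise ConfigurationError("min_probes must be >= 1")
        if self.max_gap < 0:
            raise ConfigurationError("max_gap must be >= 0")
        if self.n_permutations < 1:
            raise ConfigurationError("n_permutations must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigurationError("alpha must lie in (0, 1)")

    def threshold_grid(self, score: np.ndarray) -> np.ndarray:
        if self.thresholds is not None:
            grid = np.asarray(self.thresholds, dtype=float)
        else:
            grid = np.quantile(score, np.asarray(self.threshold_quantiles))
        grid = np.unique(grid)
        if grid.size == 0:
            raise ConfigurationError("threshold grid is empty")
        return grid


@dataclass(frozen=True)
class Peak:
    """One binding locus: a qualifying probe run (0-based half-open)."""

    chrom: str
    start: int
    end: int
    peak_score: float  # max probe score inside the run
    n_probes: int  # number of supra-threshold probes

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ConfigurationError("peak end must exceed start")


@dataclass
class FDRCurve:
    """Observed/null peak counts and the FDR estimate per candidate threshold."""

    frame: pd.DataFrame  # threshold, n_observed, null_mean, fdr_raw, fdr

    def selected_threshold(self, alpha: float) -> float | None:
        """Smallest grid threshold with adjusted FDR strictly below alpha."""
        ok = self.frame[self.frame["fdr"] < alpha]
        if ok.empty:
            return None
        return float(ok["threshold"].iloc[0])


def _run_groups(above: np.ndarray, max_gap: int) -> list[np.ndarray]:
    """Indices of supra-threshold probes, grouped into gap-tolerant runs."""
    hits = np.flatnonzero(above)
    if hits.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(hits) > max_gap + 1)
    return np.split(hits, breaks + 1)


def _count_runs(above: np.ndarray, min_probes: int, max_gap: int) -> int:
    hits = np.flatnonzero(above)
    if hits.size == 0:
        return 0
    if min_probes == 1 and max_gap == 0:
        return 1 + int(np.sum(np.diff(hits) > 1))
    breaks = np.diff(hits) > max_gap + 1
    group_ids = np.concatenate([[0], np.cumsum(breaks)])
    sizes = np.bincount(group_ids)
    return int(np.sum(sizes >= min_probes))


def find_runs(
    track: ScoreTrack, threshold: float, min_probes: int = 4, max_gap: int = 1
) -> list[Peak]:
    """All qualifying peaks at a fixed threshold, per chromosome."""
    peaks: list[Peak] = []
    start = track.probes["start"].to_numpy()
    end = track.probes["end"].to_numpy()
    for chrom, sl in track.chrom_slices().items():
        above = track.score[sl] >= threshold
        for group in _run_groups(above, max_gap):
            if group.size < min_probes:
                continue
            lo = sl.start + group[0]
            hi = sl.start + group[-1]
            peaks.append(
                Peak(
                    chrom=chrom,
                    start=int(start[lo]),
                    end=int(end[hi]),
                    peak_score=float(track.score[lo : hi + 1].max()),
                    n_probes=int(group.size),
                )
            )
    return peaks


def count_peaks(
    track_score_by_chrom: Sequence[np.ndarray],
    threshold: float,
    min_probes: int,
    max_gap: int,
) -> int:
    return sum(
        _count_runs(s >= threshold, min_probes, max_gap) for s in track_score_by_chrom
    )


def permute_track(
    track: ScoreTrack,
    rng: np.random.Generator | int,
    per_chromosome: bool = True,
) -> ScoreTrack:
    """Shuffle scores uniformly among probe positions, within each chromosome
    by default; probe positions are untouched and each chromosome keeps its
    exact score multiset."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    score = track.score.copy()
    if per_chromosome:
        for sl in track.chrom_slices().values():
            score[sl] = rng.permutation(score[sl])
    else:
        score = rng.permutation(score)
    return ScoreTrack(
        probes=track.probes,
        score=score,
        provenance=dict(track.provenance, permuted=True),
    )


def _scores_by_chrom(track: ScoreTrack) -> list[np.ndarray]:
    return [track.score[sl] for sl in track.chrom_slices().values()]


def estimate_fdr_curve(track: ScoreTrack, params: PeakCallParams) -> FDRCurve:
    """Monte-Carlo FDR over the threshold grid.

    For each threshold t: FDR_raw(t) = min(1, mean null count / max(1,
    observed count)); the final estimate is the running minimum over
    increasing t, making the curve monotone non-increasing.
    """
    grid = params.threshold_grid(track.score)
    observed = np.array(
        [
            count_peaks(_scores_by_chrom(track), t, params.min_probes, params.max_gap)
            for t in grid
        ],
        dtype=float,
    )
    null_total = np.zeros(grid.size)
    chrom_scores = _scores_by_chrom(track)
    for r in range(params.n_permutations):
        rng = np.random.default_rng(params.seed + r)
        if params.per_chromosome:
            permuted = [rng.permutation(s) for s in chrom_scores]
        else:
            flat = rng.permutation(np.concatenate(chrom_scores))
            sizes = np.cumsum([s.size for s in chrom_scores])[:-1]
            permuted = np.split(flat, sizes)
        for i, t in enumerate(grid):
            null_total[i] += count_peaks(permuted, t, params.min_probes, params.max_gap)
    null_mean = null_total / params.n_permutations
    fdr_raw = np.minimum(1.0, null_mean / np.maximum(observed, 1.0))
    fdr = np.minimum.accumulate(fdr_raw)
    frame = pd.DataFrame(
        {
            "threshold": grid,
            "n_observed": observed.astype(int),
            "null_mean": null_mean,
            "fdr_raw": fdr_raw,
            "fdr": fdr,
        }
    )
    return FDRCurve(frame=frame)


def call_peaks_fdr(
    track: ScoreTrack,
    params: PeakCallParams = PeakCallParams(),
    genome: Mapping[str, int] | None = None,
    factor_name: str | None = None,
) -> tuple[LocusSet, FDRCurve]:
    """Select binding loci at the permutation-FDR threshold.

    Returns an empty locus set when no grid threshold reaches the target
    FDR. ``genome`` supplies chromosome lengths for the locus set; when
    omitted they are inferred from the last probe end per chromosome.
    """
    curve = estimate_fdr_curve(track, params)
    threshold = curve.selected_threshold(params.alpha)
    name = factor_name or str(track.provenance.get("factor", "peaks"))
    if genome is None:
        genome = {
            chrom: int(track.probes["end"].to_numpy()[sl.stop - 1])
            for chrom, sl in track.chrom_slices().items()
        }
    if threshold is None:
        loci = LocusSet(name, [], genome, metadata={"threshold": None, "fdr": None})
        return loci, curve
    peaks = find_runs(track, threshold, params.min_probes, params.max_gap)
    achieved = float(
        curve.frame.loc[curve.frame["threshold"] == threshold, "fdr"].iloc[0]
    )
    loci = LocusSet(
        name,
        [(p.chrom, p.start, p.end, p.peak_score) for p in peaks],
        genome,
        metadata={
            "threshold": threshold,
            "fdr": achieved,
            "alpha": params.alpha,
            "n_permutations": params.n_permutations,
            "seed": params.seed,
        },
    )
    return loci, curve
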