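"""Co-localization statistics for binding-locus sets and score tracks.

A :class:`LocusSet` is a factor's binding loci on a fixed genome. Overlap is
counted in loci (a locus of A "overlaps" B when it intersects any locus of B
by at least 1 bp), matching how Venn diagrams of binding loci are drawn.
The enrichment null re-places each locus of A uniformly at random on its own
chromosome with its length preserved, leaving B fixed; the fold enrichment
is the observed count over the null mean and the p-value is the standard
add-one empirical tail probability, with floor 1/(n_shuffles + 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigurationError, GridMismatchError
from .io import IntervalRecord, ScoreTrack


def merge_intervals(
    intervals: Sequence[tuple[str, int, int, float]],
) -> list[tuple[str, int, int, float]]:
    """Merge overlapping (>= 1 bp) intervals per chromosome; keep max score.

    Bookended intervals ([a,b) and [b,c)) share no base and stay separate.
    Chromosome blocks keep their first-appearance order.
    """
    by_chrom: dict[str, list[tuple[int, int, float]]] = {}
    for chrom, start, end, score in intervals:
        by_chrom.setdefault(chrom, []).append((start, end, score))
    merged: list[tuple[str, int, int, float]] = []
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        cur_s, cur_e, cur_v = ivs[0]
        for s, e, v in ivs[1:]:
            if s < cur_e:  # true overlap
                cur_e = max(cur_e, e)
                cur_v = max(cur_v, v)
            else:
                merged.append((chrom, cur_s, cur_e, cur_v))
                cur_s, cur_e, cur_v = s, e, v
        merged.append((chrom, cur_s, cur_e, cur_v))
    return merged


class LocusSet:
    """Non-overlapping binding loci of one factor on a fixed genome.

    Overlapping input intervals are merged on construction (analysis sets are
    interval unions); shuffled placements produced internally skip the merge
    so that the null counts loci, not merged fragments.
    """

    def __init__(
        self,
        name: str,
        intervals: Sequence[IntervalRecord | tuple],
        genome: Mapping[str, int],
        metadata: dict | None = None,
        merge: bool = True,
    ) -> None:
        raw: list[tuple[str, int, int, float]] = []
        for iv in intervals:
            if isinstance(iv, IntervalRecord):
                raw.append((iv.chrom, iv.start, iv.end, iv.score))
            else:
                chrom, start, end = iv[0], int(iv[1]), int(iv[2])
                score = float(iv[3]) if len(iv) > 3 else 0.0
                raw.append((chrom, start, end, score))
        if merge and raw:
            raw = merge_intervals(raw)
        self.name = name
        self.genome = dict(genome)
        self.metadata = dict(metadata or {})
        for chrom, start, end, _ in raw:
            if chrom not in self.genome:
                raise ConfigurationError(f"locus on unknown chromosome {chrom!r}")
            if start < 0 or end > self.genome[chrom]:
                raise ConfigurationError(
                    f"locus [{start}, {end}) outside {chrom} (length {self.genome[chrom]})"
                )
            if end <= start:
                raise ConfigurationError(f"empty locus [{start}, {end}) on {chrom}")
        self._intervals = tuple(raw)

    def __len__(self) -> int:
        return len(self._intervals)

    def __iter__(self):
        return iter(self._intervals)

    @property
    def intervals(self) -> tuple[tuple[str, int, int, float], ...]:
        return self._intervals

    @property
    def records(self) -> list[IntervalRecord]:
        return [
            IntervalRecord(c, s, e, self.name, v) for c, s, e, v in self._intervals
        ]

    def lengths(self) -> np.ndarray:
        return np.array([e - s for _, s, e, _ in self._intervals], dtype=np.int64)

    def by_chrom(self) -> dict[str, np.ndarray]:
        """Per chromosome: array of (start, end) rows, sorted by start."""
        out: dict[str, list[tuple[int, int]]] = {}
        for c, s, e, _ in self._intervals:
            out.setdefault(c, []).append((s, e))
        return {
            c: np.array(sorted(ivs), dtype=np.int64).reshape(-1, 2)
            for c, ivs in out.items()
        }

    @classmethod
    def from_records(
        cls,
        name: str,
        records: Sequence[IntervalRecord],
        genome: Mapping[str, int],
        **kwargs,
    ) -> "LocusSet":
        return cls(name, records, genome, **kwargs)


def _check_same_genome(a: LocusSet, b: LocusSet) -> None:
    if a.genome != b.genome:
        raise ConfigurationError(
            f"locus sets {a.name!r} and {b.name!r} use different genome references"
        )


def shared_loci(a: LocusSet, b: LocusSet) -> LocusSet:
    """Intersection regions (>= 1 bp) of two locus sets, merged."""
    _check_same_genome(a, b)
    b_chrom = b.by_chrom()
    pieces: list[tuple[str, int, int, float]] = []
    for chrom, s, e, v in a.intervals:
        ivs = b_chrom.get(chrom)
        if ivs is None:
            continue
        for bs, be in ivs:
            lo, hi = max(s, bs), min(e, be)
            if hi > lo:
                pieces.append((chrom, int(lo), int(hi), v))
    return LocusSet(f"{a.name}&{b.name}", pieces, a.genome)


def _overlaps_any(sorted_ivs: np.ndarray, start: int, end: int) -> bool:
    """Does [start, end) intersect any of the disjoint sorted intervals?"""
    if sorted_ivs.size == 0:
        return False
    idx = int(np.searchsorted(sorted_ivs[:, 0], end, side="left"))
    return idx > 0 and sorted_ivs[idx - 1, 1] > start


def overlap_count(a: LocusSet, b: LocusSet) -> int:
    """Number of loci of ``a`` intersecting (>= 1 bp) any locus of ``b``."""
    _check_same_genome(a, b)
    b_chrom = b.by_chrom()
    count = 0
    for chrom, s, e, _ in a.intervals:
        ivs = b_chrom.get(chrom)
        if ivs is not None and _overlaps_any(ivs, s, e):
            count += 1
    return count


def shuffle_intervals(
    a: LocusSet, rng: np.random.Generator | int, no_self_overlap: bool = False
) -> LocusSet:
    """Re-place each locus uniformly at random on its own chromosome.

    Lengths are preserved; by default shuffled loci may overlap each other
    (the unbiased placement null). With ``no_self_overlap`` placements are
    rejection-sampled to stay disjoint.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    placed: list[tuple[str, int, int, float]] = []
    by_chrom_placed: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e, v in a.intervals:
        length = e - s
        chrom_len = a.genome[chrom]
        if length > chrom_len:
            raise ConfigurationError(
                f"locus of length {length} cannot fit on {chrom} (length {chrom_len})"
            )
        for _ in range(10000):
            new_start = int(rng.integers(0, chrom_len - length + 1))
            new_end = new_start + length
            if no_self_overlap and any(
                new_start < pe and new_end > ps
                for ps, pe in by_chrom_placed.get(chrom, ())
            ):
                continue
            break
        else:
            raise ConfigurationError("could not place shuffled locus without overlap")
        placed.append((chrom, new_start, new_end, v))
        by_chrom_placed.setdefault(chrom, []).append((new_start, new_end))
    return LocusSet(a.name, placed, a.genome, merge=False)


@dataclass
class OverlapStats:
    """Observed vs shuffled-placement overlap between two locus sets."""

    observed: int
    null_mean: float
    null_sd: float
    fold: float
    p_value: float
    n_shuffles: int
    null_counts: np.ndarray = field(repr=False, default_factory=lambda: np.empty(0))

    def null_band(self, lower: float = 0.025, upper: float = 0.975) -> tuple[float, float]:
        """Central quantile band of the null overlap counts."""
        return (
            float(np.quantile(self.null_counts, lower)),
            float(np.quantile(self.null_counts, upper)),
        )


def overlap_enrichment(
    a: LocusSet,
    b: LocusSet,
    n_shuffles: int = 1000,
    rng: np.random.Generator | int = 0,
    no_self_overlap: bool = False,
) -> OverlapStats:
    """Fold enrichment of the A-over-B locus overlap vs random placement.

    Shuffles A only (B fixed). fold = observed / null_mean (infinity when the
    null mean is 0); p = (1 + #{null >= observed}) / (1 + n_shuffles).
    """
    if n_shuffles < 1:
        raise ConfigurationError("n_shuffles must be >= 1")
    _check_same_genome(a, b)
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    observed = overlap_count(a, b)
    null = np.empty(n_shuffles, dtype=np.int64)
    for i in range(n_shuffles):
        null[i] = overlap_count(
            shuffle_intervals(a, rng, no_self_overlap=no_self_overlap), b
        )
    null_mean = float(null.mean())
    null_sd = float(null.std(ddof=1)) if n_shuffles > 1 else 0.0
    fold = observed / null_mean if null_mean > 0 else float("inf")
    p = (1 + int(np.sum(null >= observed))) / (1 + n_shuffles)
    return OverlapStats(
        observed=observed,
        null_mean=null_mean,
        null_sd=null_sd,
        fold=fold,
        p_value=p,
        n_shuffles=n_shuffles,
        null_counts=null,
    )


@dataclass
class VennCounts:
    """Per-set locus counts in each exclusive Venn region.

    ``counts[set_name][membership]`` is the number of that set's loci whose
    overlap pattern is exactly ``membership`` (a sorted tuple of set names,
    always including the set itself). A locus of A overlapping B may cover
    several B loci, so the per-set accountings need not agree cell by cell.
    """

    set_names: tuple[str, ...]
    counts: dict[str, dict[tuple[str, ...], int]]

    def total(self, set_name: str) -> int:
        return sum(self.counts[set_name].values())


def venn_counts(sets: Sequence[LocusSet]) -> VennCounts:
    """Classify every locus of every set by which other sets it touches."""
    if not 2 <= len(sets) <= 3:
        raise ConfigurationError("venn_counts supports 2 or 3 locus sets")
    names = [s.name for s in sets]
    if len(set(names)) != len(names):
        raise ConfigurationError("locus sets must have distinct names")
    for other in sets[1:]:
        _check_same_genome(sets[0], other)
    by_chrom = {s.name: s.by_chrom() for s in sets}
    counts: dict[str, dict[tuple[str, ...], int]] = {n: {} for n in names}
    for s in sets:
        for chrom, start, end, _ in s.intervals:
            member = {s.name}
            for other in sets:
                if other.name == s.name:
                    continue
                ivs = by_chrom[other.name].get(chrom)
                if ivs is not None and _overlaps_any(ivs, start, end):
                    member.add(other.name)
            key = tuple(sorted(member))
            counts[s.name][key] = counts[s.name].get(key, 0) + 1
    return VennCounts(set_names=tuple(names), counts=counts)


def track_correlation(x: ScoreTrack, y: ScoreTrack) -> float:
    """Pearson correlation of two score tracks over the shared probe grid."""
    if not x.same_grid(y):
        raise GridMismatchError("tracks are on different probe grids")
    if len(x) < 2:
        raise ConfigurationError("correlation needs at least 2 probes")
    xv, yv = x.score, y.score
    if np.std(xv) == 0 or np.std(yv) == 0:
        raise ConfigurationError("correlation undefined: a track has zero variance")
    return float(np.corrcoef(xv, yv)[0, 1])
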