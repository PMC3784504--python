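"""Containers and text-format readers/writers for tiling-array data.

All coordinates, in memory and on disk, are 0-based half-open (BED
convention). Chromosome names are matched by exact string comparison.

Formats handled here:

* probe tables — tab-delimited with a header: ``chrom  start  end`` followed
  by one intensity column per sample, conventionally named
  ``<channel>_rep<k>`` with channel in {ChIP, Mock, Input};
* bedGraph — one row per probe carrying a real-valued score;
* BED6 — genomic intervals with name and score;
* chrom.sizes — two-column chromosome length files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, GridMismatchError, ParseError

CHANNELS = ("ChIP", "Mock", "Input")
COORD_COLUMNS = ("chrom", "start", "end")


@dataclass(frozen=True)
class Sample:
    """One hybridised array: a (channel, biological replicate) pair.

    ``name`` is the intensity column label in the probe table.
    """

    name: str
    channel: str
    replicate: int

    def __post_init__(self) -> None:
        if self.channel not in CHANNELS:
            raise ConfigurationError(
                f"unknown channel {self.channel!r}; expected one of {CHANNELS}"
            )
        if self.replicate < 1:
            raise ConfigurationError("replicate index must be >= 1")


@dataclass(frozen=True)
class IntervalRecord:
    """A genomic interval (0-based half-open) with a name and a score."""

    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ConfigurationError(f"negative start in {self}")
        if self.end <= self.start:
            raise ConfigurationError(f"end <= start in {self}")

    @property
    def length(self) -> int:
        return self.end - self.start


def _validate_probe_frame(frame: pd.DataFrame, sample_names: Sequence[str]) -> None:
    """Raise ParseError naming the first offending 0-based row."""
    for col in COORD_COLUMNS:
        if col not in frame.columns:
            raise ParseError(f"missing required column {col!r}")
    for name in sample_names:
        if name not in frame.columns:
            raise ParseError(f"missing intensity column {name!r}")
    start = frame["start"].to_numpy()
    end = frame["end"].to_numpy()
    if not (np.issubdtype(start.dtype, np.integer) and np.issubdtype(end.dtype, np.integer)):
        raise ParseError("start/end must be integers")
    bad = np.flatnonzero(start < 0)
    if bad.size:
        raise ParseError(f"negative start at row {bad[0]}")
    bad = np.flatnonzero(end <= start)
    if bad.size:
        raise ParseError(f"end <= start at row {bad[0]}")
    chrom = frame["chrom"].to_numpy()
    # chromosomes must form contiguous blocks, starts ascending within each
    seen: set[str] = set()
    prev_chrom: str | None = None
    for i, c in enumerate(chrom):
        if c != prev_chrom:
            if c in seen:
                raise ParseError(f"chromosome {c!r} not contiguous at row {i}")
            seen.add(c)
            prev_chrom = c
        elif start[i] <= start[i - 1]:
            raise ParseError(f"probes not sorted by start at row {i}")
    for name in sample_names:
        values = frame[name].to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ParseError(f"non-numeric intensity in column {name!r}")
        bad = np.flatnonzero(~(values > 0) | ~np.isfinite(values))
        if bad.size:
            raise ParseError(
                f"non-positive or non-finite intensity in column {name!r} at row {bad[0]}"
            )


class ProbeTable:
    """Genome-ordered tiling probes with per-sample raw intensities.

    The probe grid (chrom, start, end) is shared by every sample; intensities
    are strictly positive. A table with an empty sample list is a bare probe
    grid, as produced when laying out a synthetic genome.
    """

    def __init__(
        self,
        frame: pd.DataFrame,
        samples: Sequence[Sample] = (),
        validate: bool = True,
    ) -> None:
        self.samples: tuple[Sample, ...] = tuple(samples)
        names = [s.name for s in self.samples]
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate sample column names")
        if validate:
            _validate_probe_frame(frame, names)
        self.frame = frame.reset_index(drop=True)

    # -- basic accessors -------------------------------------------------
    def __len__(self) -> int:
        return len(self.frame)

    @property
    def probes(self) -> pd.DataFrame:
        """The (chrom, start, end) grid as a DataFrame view."""
        return self.frame[list(COORD_COLUMNS)]

    @property
    def chroms(self) -> list[str]:
        return list(dict.fromkeys(self.frame["chrom"]))

    def midpoints(self) -> np.ndarray:
        return (
            self.frame["start"].to_numpy() + self.frame["end"].to_numpy()
        ) / 2.0

    def intensity(self, sample: Sample | str) -> np.ndarray:
        name = sample.name if isinstance(sample, Sample) else sample
        return self.frame[name].to_numpy(dtype=float)

    def samples_for(self, channel: str) -> list[Sample]:
        return sorted(
            (s for s in self.samples if s.channel == channel),
            key=lambda s: s.replicate,
        )

    def sample(self, channel: str, replicate: int) -> Sample:
        for s in self.samples:
            if s.channel == channel and s.replicate == replicate:
                return s
        raise ConfigurationError(f"no sample for channel {channel!r} replicate {replicate}")

    def same_grid(self, other: "ProbeTable | ScoreTrack") -> bool:
        mine = self.probes
        theirs = other.probes if isinstance(other, ScoreTrack) else other.probes
        return mine.reset_index(drop=True).equals(theirs.reset_index(drop=True))


@dataclass
class ScoreTrack:
    """One real value per probe on a fixed grid, with provenance metadata."""

    probes: pd.DataFrame  # columns chrom, start, end
    score: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.score = np.asarray(self.score, dtype=float)
        if len(self.probes) != len(self.score):
            raise GridMismatchError(
                f"{len(self.probes)} probes but {len(self.score)} scores"
            )
        self.probes = self.probes.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.score)

    @property
    def chroms(self) -> list[str]:
        return list(dict.fromkeys(self.probes["chrom"]))

    def chrom_slices(self) -> dict[str, slice]:
        """Contiguous row slice per chromosome, in grid order."""
        chrom = self.probes["chrom"].to_numpy()
        out: dict[str, slice] = {}
        if len(chrom) == 0:
            return out
        boundaries = np.flatnonzero(chrom[1:] != chrom[:-1]) + 1
        edges = np.concatenate([[0], boundaries, [len(chrom)]])
        for lo, hi in zip(edges[:-1], edges[1:]):
            out[chrom[lo]] = slice(int(lo), int(hi))
        return out

    def same_grid(self, other: "ScoreTrack") -> bool:
        return self.probes.equals(other.probes)


# ---------------------------------------------------------------------------
# probe tables
# ---------------------------------------------------------------------------

def read_probe_table(
    path: str | Path,
    sample_manifest: Mapping[str, tuple[str, int]],
) -> ProbeTable:
    """Read a tab-delimited probe table.

    ``sample_manifest`` maps intensity column names to (channel, replicate).
    Errors name the offending file line (1-based, counting the header).
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t")
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"{path}: {exc}") from exc
    samples = [
        Sample(name=col, channel=ch, replicate=rep)
        for col, (ch, rep) in sample_manifest.items()
    ]
    try:
        return ProbeTable(frame, samples)
    except ParseError as exc:
        msg = str(exc)
        # translate 0-based row indices into file line numbers (header = line 1)
        import re

        m = re.search(r"at row (\d+)", msg)
        if m:
            line = int(m.group(1)) + 2
            msg = msg[: m.start()] + f"at line {line}"
        raise ParseError(f"{path}: {msg}") from exc


def write_probe_table(table: ProbeTable, path: str | Path) -> None:
    table.frame.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_sample_manifest(path: str | Path) -> dict[str, tuple[str, int]]:
    """Read a TSV manifest with columns: column, channel, replicate."""
    frame = pd.read_csv(path, sep="\t")
    for col in ("column", "channel", "replicate"):
        if col not in frame.columns:
            raise ParseError(f"{path}: manifest missing column {col!r}")
    return {
        str(r.column): (str(r.channel), int(r.replicate))
        for r in frame.itertuples(index=False)
    }


# ---------------------------------------------------------------------------
# bedGraph / BED / chrom.sizes
# ---------------------------------------------------------------------------

def _format_score(x: float) -> str:
    if float(x) == int(x):
        return str(int(x))
    return repr(float(x))


def write_bedgraph(track: ScoreTrack, path: str | Path) -> None:
    """Write one bedGraph row per probe interval (no track line)."""
    with open(path, "w") as fh:
        chrom = track.probes["chrom"].to_numpy()
        start = track.probes["start"].to_numpy()
        end = track.probes["end"].to_numpy()
        for c, s, e, v in zip(chrom, start, end, track.score):
            fh.write(f"{c}\t{s}\t{e}\t{_format_score(v)}\n")


def read_bedgraph(path: str | Path) -> ScoreTrack:
    rows: list[tuple[str, int, int, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ParseError(f"{path}: expected 4 columns at line {lineno}")
            try:
                rows.append((parts[0], int(parts[1]), int(parts[2]), float(parts[3])))
            except ValueError as exc:
                raise ParseError(f"{path}: malformed value at line {lineno}") from exc
    frame = pd.DataFrame(rows, columns=["chrom", "start", "end", "score"])
    return ScoreTrack(
        probes=frame[list(COORD_COLUMNS)],
        score=frame["score"].to_numpy() if len(frame) else np.empty(0),
        provenance={"source": str(path)},
    )


BED_HEADER = "# chrom\tstart\tend\tname\tscore\tstrand"


def write_bed(records: Iterable[IntervalRecord], path: str | Path) -> None:
    """Write BED6 (strand '.'), with a comment header line."""
    with open(path, "w") as fh:
        fh.write(BED_HEADER + "\n")
        for r in records:
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\t{_format_score(r.score)}\t.\n"
            )


def read_bed(path: str | Path) -> list[IntervalRecord]:
    records: list[IntervalRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}: fewer than 3 columns at line {lineno}")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ParseError(f"{path}: non-integer coordinate at line {lineno}") from exc
            name = parts[3] if len(parts) > 3 else "."
            try:
                score = float(parts[4]) if len(parts) > 4 else 0.0
            except ValueError as exc:
                raise ParseError(f"{path}: non-numeric score at line {lineno}") from exc
            if end <= start:
                raise ParseError(f"{path}: end <= start at line {lineno}")
            if start < 0:
                raise ParseError(f"{path}: negative start at line {lineno}")
            records.append(IntervalRecord(parts[0], start, end, name, score))
    return records


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ParseError(f"{path}: expected 2 columns at line {lineno}")
            try:
                sizes[parts[0]] = int(parts[1])
            except ValueError as exc:
                raise ParseError(f"{path}: non-integer length at line {lineno}") from exc
            if sizes[parts[0]] <= 0:
                raise ParseError(f"{path}: non-positive length at line {lineno}")
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, length in sizes.items():
            fh.write(f"{name}\t{length}\n")
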