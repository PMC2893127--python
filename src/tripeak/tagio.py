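"""Reading and writing the genomic file formats the pipeline touches.

All coordinates are 0-based half-open (BED-native).  A sequencing tag is
reduced to its 5'-most mapped base and strand: for a ``+`` alignment that is
the BED start, for a ``-`` alignment it is ``end - 1``.  Read length is
discarded -- downstream steps only use tag start positions together with the
known maximum fragment size *d*.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

FORWARD = "+"
REVERSE = "-"
_STRANDS = (FORWARD, REVERSE)

#: default read length used when materializing tags back into BED intervals
DEFAULT_READ_LENGTH = 36


class BedParseError(ValueError):
    """A malformed line in a BED file (carries the 1-based line number)."""


class CoordinateError(ValueError):
    """A coordinate outside the chromosome bounds."""


@dataclass(frozen=True, order=True)
class TagRecord:
    """One uniquely mapped sequencing tag: chromosome, 5' position, strand."""

    chrom: str
    pos: int
    strand: str

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise CoordinateError(f"negative tag position {self.pos}")
        if self.strand not in _STRANDS:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass(frozen=True)
class Region:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise CoordinateError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def __str__(self) -> str:  # pragma: no cover - convenience
        return f"{self.chrom}:{self.start}-{self.end}"


class GenomeTable:
    """Ordered map of chromosome name to length in bp."""

    def __init__(self, items: Iterable[tuple[str, int]]):
        self._lengths: dict[str, int] = {}
        for name, length in items:
            if name in self._lengths:
                raise ValueError(f"duplicate chromosome name {name!r}")
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length")
            self._lengths[name] = int(length)
        if not self._lengths:
            raise ValueError("empty genome table")

    @classmethod
    def from_file(cls, path: str | Path) -> "GenomeTable":
        """Read a two-column whitespace-separated name/length table."""
        items = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                fields = line.split()
                if len(fields) < 2:
                    raise BedParseError(
                        f"{path}:{lineno}: expected 'name length', got {line!r}"
                    )
                try:
                    items.append((fields[0], int(fields[1])))
                except ValueError as exc:
                    raise BedParseError(f"{path}:{lineno}: bad length field") from exc
        return cls(items)

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, length in self._lengths.items():
                fh.write(f"{name}\t{length}\n")

    def __contains__(self, name: str) -> bool:
        return name in self._lengths

    def __getitem__(self, name: str) -> int:
        return self._lengths[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self._lengths)

    def __len__(self) -> int:
        return len(self._lengths)

    def items(self) -> Iterable[tuple[str, int]]:
        return self._lengths.items()

    @property
    def names(self) -> list[str]:
        return list(self._lengths)

    @property
    def total_length(self) -> int:
        return sum(self._lengths.values())


_SKIP_PREFIXES = ("track", "browser", "#")


def read_tags(path: str | Path, genome: GenomeTable) -> list[TagRecord]:
    """Read mapped tags from a BED6(+) file.

    ``+`` records contribute their start, ``-`` records their ``end - 1``.
    Records on chromosomes absent from *genome* are dropped; track/browser
    and comment lines are skipped.  Malformed lines raise
    :class:`BedParseError` naming the line; out-of-bounds coordinates raise
    :class:`CoordinateError`.
    """
    tags: list[TagRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(_SKIP_PREFIXES):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise BedParseError(
                    f"{path}:{lineno}: expected >=6 BED columns, got {len(fields)}"
                )
            chrom, strand = fields[0], fields[5]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if strand not in _STRANDS:
                raise BedParseError(f"{path}:{lineno}: bad strand {strand!r}")
            if chrom not in genome:
                continue
            if not (0 <= start < end):
                raise CoordinateError(f"{path}:{lineno}: invalid interval")
            if end > genome[chrom]:
                raise CoordinateError(
                    f"{path}:{lineno}: end {end} beyond {chrom} length {genome[chrom]}"
                )
            pos = start if strand == FORWARD else end - 1
            tags.append(TagRecord(chrom, pos, strand))
    return tags


def write_tags(
    tags: Sequence[TagRecord],
    path: str | Path,
    genome: GenomeTable,
    read_length: int = DEFAULT_READ_LENGTH,
) -> None:
    """Write tags as BED6 reads of *read_length* bp (clipped at chromosome
    ends so that the strand-aware 5' convention round-trips exactly)."""
    with open(path, "w") as fh:
        for i, tag in enumerate(tags):
            clen = genome[tag.chrom]
            if tag.strand == FORWARD:
                start, end = tag.pos, min(clen, tag.pos + read_length)
            else:
                start, end = max(0, tag.pos + 1 - read_length), tag.pos + 1
            fh.write(f"{tag.chrom}\t{start}\t{end}\ttag{i}\t0\t{tag.strand}\n")


def deduplicate_tags(tags: Sequence[TagRecord]) -> tuple[list[TagRecord], int]:
    """Keep at most one tag per (chrom, pos, strand), preserving the order of
    first occurrence.  Returns ``(unique_tags, n_removed)``."""
    seen: set[TagRecord] = set()
    out: list[TagRecord] = []
    for tag in tags:
        if tag not in seen:
            seen.add(tag)
            out.append(tag)
    return out, len(tags) - len(out)


@dataclass(frozen=True)
class ScoredRegion:
    """One output row of the final ranked region list."""

    region: Region
    rank: int
    combined: float
    p_c: float
    d_p: float
    p_m: float | None


_HEADER = "#chrom\tstart\tend\tname\tscore\tstrand\tp_c\td_p\tp_m\n"


def _fmt(x: float | None) -> str:
    return "NA" if x is None else format(x, ".8g")


def write_scored_regions(rows: Sequence[ScoredRegion], path: str | Path) -> None:
    """Write the ranked regions as BED6+3 (name = rank, score = combined
    evidence score, extra columns p_c, d_p, p_m), ordered by rank."""
    ranks = sorted(r.rank for r in rows)
    if ranks != list(range(1, len(rows) + 1)):
        raise ValueError("ranks must be a permutation of 1..N")
    with open(path, "w") as fh:
        fh.write(_HEADER)
        for row in sorted(rows, key=lambda r: r.rank):
            reg = row.region
            fh.write(
                f"{reg.chrom}\t{reg.start}\t{reg.end}\t{row.rank}\t"
                f"{_fmt(row.combined)}\t.\t{_fmt(row.p_c)}\t{_fmt(row.d_p)}\t"
                f"{_fmt(row.p_m)}\n"
            )


def read_scored_regions(path: str | Path) -> list[ScoredRegion]:
    rows: list[ScoredRegion] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 9:
                raise BedParseError(f"{path}:{lineno}: expected 9 columns")
            rows.append(
                ScoredRegion(
                    region=Region(f[0], int(f[1]), int(f[2])),
                    rank=int(f[3]),
                    combined=float(f[4]),
                    p_c=float(f[6]),
                    d_p=float(f[7]),
                    p_m=None if f[8] == "NA" else float(f[8]),
                )
            )
    return rows
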