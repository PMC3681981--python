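"""Genomic file I/O with a single fixed coordinate convention.

All coordinates held in memory are 0-based half-open (BED-native).
1-based inputs (TSS tables, region strings on the command line) are
converted exactly once, at the reader boundary.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "FormatError",
    "GenomeLayout",
    "GenomicInterval",
    "TagAlignment",
    "TagLibrary",
    "TssRecord",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_bed",
    "write_bed",
    "read_tss_table",
    "write_tss_table",
    "parse_region",
    "format_region",
]

_STRANDS = ("+", "-", ".")


class FormatError(ValueError):
    """A malformed input file or record."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval [start, end) on ``chrom``."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )
        if self.strand not in _STRANDS:
            raise ValueError(f"strand must be one of {_STRANDS}, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """>= 1 bp overlap on the same chromosome."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass(frozen=True)
class TagAlignment:
    """One aligned small-RNA tag with a multi-mapping weight in (0, 1].

    A tag mapping to k genomic locations carries weight 1/k at each, so
    library totals over all placements count each sequenced tag once.
    """

    interval: GenomicInterval
    weight: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.weight <= 1.0):
            raise ValueError(f"weight must be in (0, 1], got {self.weight}")


@dataclass
class TagLibrary:
    """A collection of weighted tag alignments plus the library total.

    ``library_total`` is the sum of weights over the whole sequenced
    library *before* any regional subsetting; the stored tags may be a
    subset, so ``library_total`` may exceed their summed weight. It is
    the denominator of tags-per-million normalization.
    """

    tags: list[TagAlignment] = field(default_factory=list)
    library_total: float | None = None

    def __post_init__(self) -> None:
        stored = self.stored_weight
        if self.library_total is None:
            self.library_total = stored
        if self.library_total < 0 or (self.library_total == 0 and self.tags):
            raise ValueError("library_total must be positive")
        # an empty library may carry total 0; normalization rejects the
        # zero denominator downstream
        if self.library_total < stored - 1e-9:
            raise ValueError(
                f"library_total ({self.library_total}) is below the summed "
                f"weight of stored tags ({stored})"
            )

    @property
    def stored_weight(self) -> float:
        return float(sum(t.weight for t in self.tags))

    def __len__(self) -> int:
        return len(self.tags)

    def __iter__(self):
        return iter(self.tags)


@dataclass(frozen=True)
class TssRecord:
    """A RefSeq-style transcription start site (1-based coordinate)."""

    chrom: str
    position: int  # 1-based
    strand: str
    gene_id: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"TSS position must be >= 1, got {self.position}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"TSS strand must be + or -, got {self.strand!r}")

    @property
    def position0(self) -> int:
        """0-based TSS coordinate."""
        return self.position - 1


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome names and lengths: the sampling universe."""

    chromosomes: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        names = [n for n, _ in self.chromosomes]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate chromosome names: {dupes}")
        for name, length in self.chromosomes:
            if length < 1:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, int]]) -> "GenomeLayout":
        return cls(tuple((str(n), int(l)) for n, l in pairs))

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.chromosomes)

    @property
    def total_length(self) -> int:
        return sum(l for _, l in self.chromosomes)

    def __contains__(self, name: str) -> bool:
        return any(n == name for n, _ in self.chromosomes)

    def length_of(self, name: str) -> int:
        for n, l in self.chromosomes:
            if n == name:
                return l
        raise KeyError(f"unknown chromosome {name!r}")

    def validate_interval(self, interval: GenomicInterval) -> None:
        if interval.chrom not in self:
            raise ValueError(f"unknown chromosome {interval.chrom!r}")
        clen = self.length_of(interval.chrom)
        if interval.end > clen:
            raise ValueError(
                f"interval {format_region(interval)} exceeds length "
                f"{clen} of chromosome {interval.chrom}"
            )


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_chrom_sizes(path: str | Path) -> GenomeLayout:
    """Read a two-column ``chrom.sizes`` file (name, length) preserving order."""
    pairs: list[tuple[str, int]] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) < 2:
                raise FormatError(f"{path}: line {lineno}: expected 2 columns")
            name = fields[0]
            try:
                length = int(fields[1])
            except ValueError:
                raise FormatError(
                    f"{path}: line {lineno}: non-integer length {fields[1]!r}"
                ) from None
            if length < 1:
                raise FormatError(
                    f"{path}: line {lineno}: non-positive length {length}"
                )
            if name in seen:
                raise FormatError(
                    f"{path}: line {lineno}: duplicate chromosome {name!r}"
                )
            seen.add(name)
            pairs.append((name, length))
    if not pairs:
        raise FormatError(f"{path}: no chromosomes")
    return GenomeLayout.from_pairs(pairs)


def write_chrom_sizes(layout: GenomeLayout, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, length in layout.chromosomes:
            fh.write(f"{name}\t{length}\n")


def _parse_bed_line(fields: list[str], path, lineno: int) -> tuple[GenomicInterval, str, float]:
    if len(fields) < 3:
        raise FormatError(f"{path}: line {lineno}: expected >= 3 BED columns")
    chrom = fields[0]
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError:
        raise FormatError(f"{path}: line {lineno}: non-integer coordinates") from None
    if start < 0 or start >= end:
        raise FormatError(
            f"{path}: line {lineno}: invalid interval [{start}, {end})"
        )
    name = fields[3] if len(fields) > 3 else "."
    weight = 1.0
    if len(fields) > 4:
        try:
            weight = float(fields[4])
        except ValueError:
            weight = 1.0  # non-numeric score: fall back to unit weight
    strand = fields[5] if len(fields) > 5 and fields[5] in _STRANDS else "."
    return GenomicInterval(chrom, start, end, strand), name, weight


def read_bed(
    path: str | Path,
    kind: str = "tags",
    layout: GenomeLayout | None = None,
    library_total: float | None = None,
):
    """Read a BED3-BED6 file.

    kind="tags" returns a :class:`TagLibrary` (column 5, if numeric, is
    the multimap weight, else 1.0); kind="peaks" returns a list of
    :class:`GenomicInterval`. Coordinates are taken as-is (BED is
    0-based half-open).
    """
    if kind not in ("tags", "peaks"):
        raise ValueError(f"kind must be 'tags' or 'peaks', got {kind!r}")
    intervals: list[GenomicInterval] = []
    tags: list[TagAlignment] = []
    bad_chroms: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            iv, _name, weight = _parse_bed_line(line.split("\t"), path, lineno)
            if layout is not None:
                if iv.chrom not in layout:
                    bad_chroms.add(iv.chrom)
                    continue
                layout.validate_interval(iv)
            if kind == "tags":
                tags.append(TagAlignment(iv, weight))
            else:
                intervals.append(iv)
    if bad_chroms:
        raise FormatError(
            f"{path}: chromosomes not in layout: {sorted(bad_chroms)}"
        )
    if kind == "tags":
        return TagLibrary(tags, library_total=library_total)
    return intervals


def write_bed(records, path: str | Path) -> None:
    """Write a TagLibrary (BED6 with weight in the score column) or a
    sequence of GenomicInterval (BED3/BED6) to ``path``.

    Weights are written with ``repr`` so a read/write round trip is
    bit-exact.
    """
    with open(path, "w") as fh:
        if isinstance(records, TagLibrary):
            for i, tag in enumerate(records.tags):
                iv = tag.interval
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\ttag{i + 1}\t"
                    f"{tag.weight!r}\t{iv.strand}\n"
                )
        else:
            for iv in records:
                if iv.strand == ".":
                    fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
                else:
                    fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t0\t{iv.strand}\n")


def read_tss_table(path: str | Path, layout: GenomeLayout | None = None) -> list[TssRecord]:
    """Read a TSV of TSS records with header chrom, position, strand, gene_id.

    Positions are 1-based in the file. Duplicate (chrom, position, strand)
    rows are kept; deduplication happens downstream when promoter windows
    are defined.
    """
    records: list[TssRecord] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        required = ["chrom", "position", "strand", "gene_id"]
        if header[: len(required)] != required:
            raise FormatError(
                f"{path}: expected header {required}, got {header}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(f"{path}: line {lineno}: expected 4 columns")
            chrom, pos_s, strand, gene_id = fields[:4]
            try:
                position = int(pos_s)
            except ValueError:
                raise FormatError(
                    f"{path}: line {lineno}: non-integer position {pos_s!r}"
                ) from None
            if position < 1:
                raise FormatError(
                    f"{path}: line {lineno}: position must be >= 1, got {position}"
                )
            if strand not in ("+", "-"):
                raise FormatError(
                    f"{path}: line {lineno}: strand must be + or -, got {strand!r}"
                )
            rec = TssRecord(chrom, position, strand, gene_id)
            if layout is not None:
                if chrom not in layout:
                    raise FormatError(
                        f"{path}: line {lineno}: unknown chromosome {chrom!r}"
                    )
                if position > layout.length_of(chrom):
                    raise FormatError(
                        f"{path}: line {lineno}: position {position} beyond "
                        f"chromosome {chrom} length"
                    )
            records.append(rec)
    return records


def write_tss_table(records: Sequence[TssRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tposition\tstrand\tgene_id\n")
        for r in records:
            fh.write(f"{r.chrom}\t{r.position}\t{r.strand}\t{r.gene_id}\n")


_REGION_RE = re.compile(r"^([^:]+):([\d,]+)-([\d,]+)$")


def parse_region(text: str) -> GenomicInterval:
    """Parse a 1-based inclusive ``chrom:start-end`` region string.

    Converts to the internal 0-based half-open convention, e.g.
    ``chr3R:12500000-12840000`` -> [12499999, 12840000).
    """
    m = _REGION_RE.match(text.strip())
    if not m:
        raise FormatError(f"cannot parse region {text!r}; expected chrom:start-end")
    chrom = m.group(1)
    start1 = int(m.group(2).replace(",", ""))
    end1 = int(m.group(3).replace(",", ""))
    if start1 < 1 or end1 < start1:
        raise FormatError(f"invalid 1-based region {text!r}")
    return GenomicInterval(chrom, start1 - 1, end1)


def format_region(interval: GenomicInterval) -> str:
    """Format as a 1-based inclusive region string (inverse of parse_region)."""
    return f"{interval.chrom}:{interval.start + 1}-{interval.end}"
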