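"""Shared genomic coordinate types, standard-format I/O, and interval overlap.

All coordinates are 0-based half-open (BED convention). BED files are read
verbatim; GTF start coordinates are shifted by -1 on input. Sequencing tags
are represented by their 5' position only — no fragment-shift or extension
is applied anywhere in the pipeline.
"""

from __future__ import annotations

import re
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from intervaltree import IntervalTree

STRANDS = ("+", "-", ".")


class BedParseError(ValueError):
    """Raised when a BED/TSV/GTF line cannot be parsed; names the line number."""


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome name -> length (bp) map."""

    lengths: dict[str, int]

    def __post_init__(self) -> None:
        if len(set(self.lengths)) != len(self.lengths):
            raise ValueError("chromosome names must be unique")
        for name, length in self.lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")

    @property
    def total_length(self) -> int:
        return int(sum(self.lengths.values()))

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths

    def __getitem__(self, chrom: str) -> int:
        return self.lengths[chrom]

    @classmethod
    def read_tsv(cls, path: str | Path) -> "GenomeLayout":
        """Read a two-column ``chrom<TAB>length`` table (a .chrom.sizes file)."""
        lengths: dict[str, int] = {}
        for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise BedParseError(f"{path}:{i}: expected 2 columns, got {len(parts)}")
            lengths[parts[0]] = int(parts[1])
        return cls(lengths)

    def write_tsv(self, path: str | Path) -> None:
        Path(path).write_text(
            "".join(f"{c}\t{l}\n" for c, l in self.lengths.items())
        )


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval, optionally stranded."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = ""

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start {self.start}")
        if not self.start < self.end:
            raise ValueError(
                f"interval {self.chrom}:{self.start}-{self.end} violates start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class GeneModel:
    """Gene with strand-aware TSS/TES anchors.

    For a + strand gene tss < tes; for a - strand gene tss > tes. ``tes`` is
    the last transcribed position exclusive-of on + and inclusive-of on -,
    i.e. both anchors come directly from the annotated (start, end) pair.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    tes: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if self.tss == self.tes:
            raise ValueError(f"gene {self.gene_id}: tss == tes")
        if self.strand == "+" and not self.tss < self.tes:
            raise ValueError(f"gene {self.gene_id}: + strand requires tss < tes")
        if self.strand == "-" and not self.tss > self.tes:
            raise ValueError(f"gene {self.gene_id}: - strand requires tss > tes")

    @property
    def start(self) -> int:
        return min(self.tss, self.tes)

    @property
    def end(self) -> int:
        return max(self.tss, self.tes)


class TagLibrary:
    """Mapped sequencing tags as per-chromosome sorted 5' positions."""

    def __init__(self, tags: dict[str, np.ndarray] | None = None) -> None:
        self.tags: dict[str, np.ndarray] = {}
        if tags:
            for chrom, pos in tags.items():
                arr = np.asarray(pos, dtype=np.int64)
                self.tags[chrom] = np.sort(arr)

    @property
    def total_tags(self) -> int:
        return int(sum(arr.size for arr in self.tags.values()))

    def chrom_tags(self, chrom: str) -> np.ndarray:
        return self.tags.get(chrom, np.empty(0, dtype=np.int64))

    def count_in(self, chrom: str, start: int, end: int) -> int:
        """Number of tags with position in [start, end)."""
        pos = self.chrom_tags(chrom)
        return int(np.searchsorted(pos, end) - np.searchsorted(pos, start))

    def validate(self, layout: GenomeLayout) -> None:
        for chrom, pos in self.tags.items():
            if chrom not in layout:
                raise ValueError(f"tag chromosome {chrom!r} not in genome layout")
            if pos.size and (pos[0] < 0 or pos[-1] >= layout[chrom]):
                raise ValueError(f"tags outside chromosome {chrom!r} bounds")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_bed(
    path: str | Path, layout: GenomeLayout | None = None
) -> list[GenomicInterval]:
    """Read BED3/BED6 into intervals, preserving file order.

    Malformed lines raise :class:`BedParseError` naming the line number;
    intervals beyond chromosome bounds raise ``ValueError`` when a layout
    is supplied.
    """
    intervals: list[GenomicInterval] = []
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise BedParseError(f"{path}:{i}: expected >=3 tab-separated columns")
        try:
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
        except ValueError as exc:
            raise BedParseError(f"{path}:{i}: non-integer coordinates") from exc
        name = parts[3] if len(parts) > 3 else ""
        strand = parts[5] if len(parts) > 5 and parts[5] in STRANDS else "."
        try:
            iv = GenomicInterval(chrom, start, end, strand, name)
        except ValueError as exc:
            raise BedParseError(f"{path}:{i}: {exc}") from exc
        if layout is not None:
            if chrom not in layout:
                raise ValueError(f"{path}:{i}: chromosome {chrom!r} not in layout")
            if end > layout[chrom]:
                raise ValueError(f"{path}:{i}: interval beyond chromosome end")
        intervals.append(iv)
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    """Write BED3 (or BED6 when any interval carries a name/strand)."""
    rows = list(intervals)
    six = any(iv.name or iv.strand != "." for iv in rows)
    with open(path, "w") as fh:
        for iv in rows:
            if six:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t0\t{iv.strand}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_tags_bed(path: str | Path, layout: GenomeLayout | None = None) -> TagLibrary:
    """Read a BED tag file into a :class:`TagLibrary` of 5' positions.

    The 5' position is ``start`` for + or unstranded records and ``end - 1``
    for - strand records.
    """
    per_chrom: dict[str, list[int]] = defaultdict(list)
    for iv in read_bed(path, layout):
        per_chrom[iv.chrom].append(iv.end - 1 if iv.strand == "-" else iv.start)
    lib = TagLibrary({c: np.array(p, dtype=np.int64) for c, p in per_chrom.items()})
    if layout is not None:
        lib.validate(layout)
    return lib


def write_tags_bed(lib: TagLibrary, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in lib.tags:
            for pos in lib.tags[chrom]:
                fh.write(f"{chrom}\t{pos}\t{pos + 1}\n")


_GTF_ATTR = re.compile(r'gene_id\s+"([^"]+)"')


def read_gene_annotation(path: str | Path, dialect: str = "tsv") -> list[GeneModel]:
    """Read gene models from a 5-column TSV or from GTF ``gene`` features.

    TSV columns: gene_id, chrom, strand, start, end (0-based half-open).
    GTF coordinates are 1-based inclusive and are converted (-1 on start).
    TSS = start for + strand genes and end for - strand genes; duplicate
    gene ids and missing strands are errors.
    """
    genes: list[GeneModel] = []
    seen: set[str] = set()

    def add(gene_id: str, chrom: str, strand: str, start: int, end: int, where: str) -> None:
        if gene_id in seen:
            raise ValueError(f"{where}: duplicate gene_id {gene_id!r}")
        seen.add(gene_id)
        if strand == "+":
            genes.append(GeneModel(gene_id, chrom, "+", tss=start, tes=end))
        elif strand == "-":
            genes.append(GeneModel(gene_id, chrom, "-", tss=end, tes=start))
        else:
            raise ValueError(f"{where}: missing or invalid strand {strand!r}")

    lines = Path(path).read_text().splitlines()
    if dialect == "tsv":
        for i, line in enumerate(lines, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise BedParseError(f"{path}:{i}: expected 5 columns")
            gene_id, chrom, strand = parts[0], parts[1], parts[2]
            start, end = int(parts[3]), int(parts[4])
            add(gene_id, chrom, strand, start, end, f"{path}:{i}")
    elif dialect == "gtf":
        for i, line in enumerate(lines, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 9:
                raise BedParseError(f"{path}:{i}: expected 9 GTF columns")
            if parts[2] != "gene":
                continue
            m = _GTF_ATTR.search(parts[8])
            if not m:
                raise BedParseError(f"{path}:{i}: no gene_id attribute")
            add(m.group(1), parts[0], parts[6], int(parts[3]) - 1, int(parts[4]),
                f"{path}:{i}")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return genes


def write_gene_annotation(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{g.start}\t{g.end}\n")


# ---------------------------------------------------------------------------
# Overlap engine
# ---------------------------------------------------------------------------

def overlap_join(
    set_a: Sequence[GenomicInterval],
    set_b: Sequence[GenomicInterval],
    min_overlap: int = 1,
) -> list[tuple[int, int]]:
    """All (a_index, b_index) pairs whose intersection is >= min_overlap bp.

    Complete: equivalent to the all-pairs intersection. Output is sorted by
    (a_index, b_index).
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for j, iv in enumerate(set_b):
        trees[iv.chrom].addi(iv.start, iv.end, j)
    pairs: list[tuple[int, int]] = []
    for i, iv in enumerate(set_a):
        tree = trees.get(iv.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(iv.start, iv.end):
            if min(iv.end, hit.end) - max(iv.start, hit.begin) >= min_overlap:
                pairs.append((i, hit.data))
    pairs.sort()
    return pairs


def distance_to_nearest_tss(
    interval: GenomicInterval, genes: Sequence[GeneModel]
) -> tuple[str, int] | None:
    """Nearest gene by |interval midpoint - TSS|, with signed genomic distance.

    The sign is midpoint - tss (genomic orientation, not strand-relative).
    Ties in |distance| go to the lexicographically smaller gene_id. Returns
    None when no gene lies on the interval's chromosome.
    """
    mid = interval.midpoint
    best: tuple[int, str, int] | None = None
    for g in genes:
        if g.chrom != interval.chrom:
            continue
        d = mid - g.tss
        key = (abs(d), g.gene_id)
        if best is None or key < (best[0], best[1]):
            best = (abs(d), g.gene_id, d)
    if best is None:
        return None
    return best[1], best[2]
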