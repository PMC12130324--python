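"""Coordinate model, interval algebra and plain-text genomic file IO.

Everything downstream speaks 0-based half-open coordinates (BED convention),
including internal types.  1-based inputs, where supported, are converted at
the reader boundary.  Strand is stored but ignored for overlap computations
(H3K27ac/ATAC signal is unstranded); it only matters for TSS resolution on
gene models.  All writers emit tab-delimited UTF-8 with deterministic
ordering and no trailing whitespace.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree

__all__ = [
    "ValidationError",
    "ParseError",
    "GenomicInterval",
    "BedInterval",
    "SignalTrack",
    "GeneModel",
    "Loop",
    "read_bed",
    "write_bed",
    "read_bedgraph",
    "read_bedpe_loops",
    "write_bedpe_loops",
    "read_gene_table",
    "write_gene_table",
    "overlap_pairs",
    "aggregate_signal",
    "sort_intervals",
]

VALID_STRANDS = ("+", "-", ".")


class ValidationError(ValueError):
    """An object violates a documented invariant."""


class ParseError(ValueError):
    """A file line cannot be interpreted; the message names the line number."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open span ``[start, end)`` on a named sequence."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("interval chrom must be non-empty")
        if self.start < 0:
            raise ValidationError(f"interval start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValidationError(
                f"interval end must exceed start, got [{self.start}, {self.end})"
            )
        if self.strand not in VALID_STRANDS:
            raise ValidationError(f"strand must be one of {VALID_STRANDS}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlap_bp(self, other: "GenomicInterval") -> int:
        """Base pairs shared with ``other`` (0 if different chrom or disjoint)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def overlaps(self, other: "GenomicInterval", min_bp: int = 1) -> bool:
        return self.overlap_bp(other) >= min_bp

    def contains_point(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class BedInterval(GenomicInterval):
    """A GenomicInterval carrying the optional BED name and score columns."""

    name: str | None = None
    score: float | None = None


def sort_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Deterministic ordering: (chrom lexicographic, start, end)."""
    return sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))


def _apply_alias(chrom: str, alias: Mapping[str, str] | None) -> str:
    if alias is None:
        return chrom
    return alias.get(chrom, chrom)


# ---------------------------------------------------------------------------
# BED / bedGraph
# ---------------------------------------------------------------------------

def read_bed(
    path: str | Path,
    alias: Mapping[str, str] | None = None,
) -> list[BedInterval]:
    """Read BED3/BED6 into validated half-open intervals, input order kept.

    Lines beginning with ``#``, ``track`` or ``browser`` are skipped.  A
    malformed or invariant-violating line raises naming its line number.
    """
    out: list[BedInterval] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: expected >=3 tab-separated columns, "
                    f"got {len(fields)}"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            name = fields[3] if len(fields) > 3 else None
            score = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: non-numeric score") from exc
            strand = fields[5] if len(fields) > 5 else "."
            try:
                out.append(
                    BedInterval(
                        chrom=_apply_alias(fields[0], alias),
                        start=start,
                        end=end,
                        strand=strand,
                        name=name,
                        score=score,
                    )
                )
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return out


def _fmt_score(score: float) -> str:
    if float(score).is_integer():
        return str(int(score))
    return repr(float(score))


def write_bed(intervals: Sequence[GenomicInterval], path: str | Path) -> None:
    """Write BED; columns extend to name/score/strand if any record has them."""
    has_name = any(getattr(iv, "name", None) is not None for iv in intervals)
    has_score = any(getattr(iv, "score", None) is not None for iv in intervals)
    has_strand = any(iv.strand != "." for iv in intervals)
    with open(path, "wt", encoding="utf-8") as fh:
        for iv in intervals:
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if has_name or has_score or has_strand:
                cols.append(str(getattr(iv, "name", None) or "."))
            if has_score or has_strand:
                score = getattr(iv, "score", None)
                cols.append(_fmt_score(score) if score is not None else ".")
            if has_strand:
                cols.append(iv.strand)
            fh.write("\t".join(cols) + "\n")


class SignalTrack:
    """Sorted, non-overlapping constant-value segments (a bedGraph in memory).

    Values are signal density per bp (arbitrary units, >= 0).  Aggregation
    over a region returns signal *mass*: value x overlapped bp, summed.
    """

    def __init__(self, segments: Iterable[tuple[str, int, int, float]]):
        per_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, value in segments:
            GenomicInterval(chrom, start, end)  # reuse invariant checks
            if not math.isfinite(value) or value < 0:
                raise ValidationError(
                    f"track value must be finite and >= 0, got {value!r}"
                )
            per_chrom.setdefault(chrom, []).append((start, end, value))
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        self._values: dict[str, np.ndarray] = {}
        for chrom, segs in per_chrom.items():
            segs.sort()
            starts = np.array([s for s, _, _ in segs], dtype=np.int64)
            ends = np.array([e for _, e, _ in segs], dtype=np.int64)
            if np.any(starts[1:] < ends[:-1]):
                raise ValidationError(f"overlapping track segments on {chrom}")
            self._starts[chrom] = starts
            self._ends[chrom] = ends
            self._values[chrom] = np.array([v for _, _, v in segs], dtype=float)

    @classmethod
    def empty(cls) -> "SignalTrack":
        return cls([])

    @classmethod
    def from_bedgraph(
        cls, path: str | Path, alias: Mapping[str, str] | None = None
    ) -> "SignalTrack":
        segs: list[tuple[str, int, int, float]] = []
        with open(path, "rt", encoding="utf-8") as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.rstrip("\n")
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                if len(fields) < 4:
                    raise ParseError(f"{path}:{lineno}: expected 4 columns")
                try:
                    segs.append(
                        (
                            _apply_alias(fields[0], alias),
                            int(fields[1]),
                            int(fields[2]),
                            float(fields[3]),
                        )
                    )
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: malformed bedGraph line") from exc
        return cls(segs)

    def to_bedgraph(self, path: str | Path) -> None:
        with open(path, "wt", encoding="utf-8") as fh:
            for chrom in sorted(self._starts):
                for s, e, v in zip(
                    self._starts[chrom], self._ends[chrom], self._values[chrom]
                ):
                    fh.write(f"{chrom}\t{s}\t{e}\t{_fmt_score(v)}\n")

    def mass(self, region: GenomicInterval) -> float:
        """Signal mass (density x bp) over ``region``; 0 where uncovered."""
        starts = self._starts.get(region.chrom)
        if starts is None or len(starts) == 0:
            return 0.0
        ends = self._ends[region.chrom]
        values = self._values[region.chrom]
        lo = int(np.searchsorted(ends, region.start, side="right"))
        hi = int(np.searchsorted(starts, region.end, side="left"))
        if hi <= lo:
            return 0.0
        ov = np.minimum(ends[lo:hi], region.end) - np.maximum(starts[lo:hi], region.start)
        ov = np.clip(ov, 0, None)
        return float(np.dot(ov.astype(float), values[lo:hi]))

    def segments(self) -> list[tuple[str, int, int, float]]:
        out = []
        for chrom in sorted(self._starts):
            out.extend(
                (chrom, int(s), int(e), float(v))
                for s, e, v in zip(
                    self._starts[chrom], self._ends[chrom], self._values[chrom]
                )
            )
        return out


def read_bedgraph(
    path: str | Path, alias: Mapping[str, str] | None = None
) -> SignalTrack:
    return SignalTrack.from_bedgraph(path, alias=alias)


def aggregate_signal(region: GenomicInterval, track: SignalTrack) -> float:
    """Signal mass of ``track`` over ``region`` (additive over partitions)."""
    return track.mass(region)


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneModel:
    """A gene body plus its strand-resolved transcription start site."""

    gene_id: str
    gene_name: str
    body: GenomicInterval
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.body.strand not in ("+", "-"):
            raise ValidationError(
                f"gene {self.gene_id}: strand must be + or - to resolve the TSS"
            )

    @property
    def tss_pos(self) -> int:
        """TSS base offset: the body's 5' end on its strand."""
        return self.body.start if self.body.strand == "+" else self.body.end - 1

    @property
    def tss(self) -> GenomicInterval:
        pos = self.tss_pos
        return GenomicInterval(self.body.chrom, pos, pos + 1, self.body.strand)


_GENE_COLUMNS = ["gene_id", "gene_name", "chrom", "start", "end", "strand", "biotype"]


def read_gene_table(
    path: str | Path, alias: Mapping[str, str] | None = None
) -> list[GeneModel]:
    """Tab-delimited gene table: gene_id, gene_name, chrom, start, end, strand, biotype."""
    genes: list[GeneModel] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#") or line.startswith("gene_id\t"):
                continue
            fields = line.split("\t")
            if len(fields) < 7:
                raise ParseError(f"{path}:{lineno}: expected 7 columns")
            try:
                body = GenomicInterval(
                    _apply_alias(fields[2], alias),
                    int(fields[3]),
                    int(fields[4]),
                    fields[5],
                )
            except (ValueError, ValidationError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            genes.append(GeneModel(fields[0], fields[1], body, fields[6]))
    return genes


def write_gene_table(genes: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("\t".join(_GENE_COLUMNS) + "\n")
        for g in genes:
            fh.write(
                "\t".join(
                    [
                        g.gene_id,
                        g.gene_name,
                        g.body.chrom,
                        str(g.body.start),
                        str(g.body.end),
                        g.body.strand,
                        g.biotype,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Loops (BEDPE + FDR)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Loop:
    """A chromatin loop: paired anchors with PET count and significance.

    Anchors are canonicalized so that, for intra-chromosomal loops, anchor1
    lies left of anchor2 (by chrom then start).
    """

    anchor1: GenomicInterval
    anchor2: GenomicInterval
    pet_count: int
    fdr: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.fdr <= 1.0):
            raise ValidationError(f"loop FDR must lie in [0, 1], got {self.fdr}")
        if self.pet_count < 0:
            raise ValidationError("PET count must be >= 0")
        a, b = self.anchor1, self.anchor2
        if (b.chrom, b.start, b.end) < (a.chrom, a.start, a.end):
            object.__setattr__(self, "anchor1", b)
            object.__setattr__(self, "anchor2", a)


def read_bedpe_loops(
    path: str | Path,
    pet_col: int = 6,
    fdr_col: int = 7,
    alias: Mapping[str, str] | None = None,
) -> list[Loop]:
    """Read loops from BEDPE with appended PET-count and FDR columns.

    ``pet_col``/``fdr_col`` are 0-based column indices (the dialect knob for
    files that interleave a name/score before the statistics).
    """
    loops: list[Loop] = []
    ncols = max(pet_col, fdr_col) + 1
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < ncols:
                raise ParseError(
                    f"{path}:{lineno}: expected >={ncols} columns, got {len(fields)}"
                )
            try:
                a1 = GenomicInterval(
                    _apply_alias(fields[0], alias), int(fields[1]), int(fields[2])
                )
                a2 = GenomicInterval(
                    _apply_alias(fields[3], alias), int(fields[4]), int(fields[5])
                )
                pet = int(float(fields[pet_col]))
                fdr = float(fields[fdr_col])
            except (ValueError, ValidationError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            try:
                loops.append(Loop(a1, a2, pet, fdr))
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return loops


def write_bedpe_loops(loops: Sequence[Loop], path: str | Path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for lp in loops:
            fh.write(
                "\t".join(
                    [
                        lp.anchor1.chrom,
                        str(lp.anchor1.start),
                        str(lp.anchor1.end),
                        lp.anchor2.chrom,
                        str(lp.anchor2.start),
                        str(lp.anchor2.end),
                        str(lp.pet_count),
                        repr(float(lp.fdr)),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Overlap engine
# ---------------------------------------------------------------------------

def overlap_pairs(
    a: Sequence[GenomicInterval],
    b: Sequence[GenomicInterval],
    min_bp: int = 1,
) -> list[tuple[int, int, int]]:
    """All (i, j, overlap_bp) with a[i] and b[j] sharing >= min_bp on one chrom.

    Strand is ignored.  Output sorted by (i, j).  Swapping the arguments
    exchanges the index columns but reports the same pair set.
    """
    if min_bp < 1:
        raise ValidationError(f"min_bp must be >= 1, got {min_bp}")
    trees: dict[str, IntervalTree] = {}
    for j, iv in enumerate(b):
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, j)
    out: list[tuple[int, int, int]] = []
    for i, iv in enumerate(a):
        tree = trees.get(iv.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(iv.start, iv.end):
            bp = min(iv.end, hit.end) - max(iv.start, hit.begin)
            if bp >= min_bp:
                out.append((i, hit.data, bp))
    out.sort(key=lambda t: (t[0], t[1]))
    return out
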