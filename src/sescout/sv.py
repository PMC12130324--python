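"""Somatic duplication recurrence over SE footprints across cancer cohorts.

A donor counts toward an SE's duplication frequency iff it carries at least
one DUP covering at least ``min_cover`` of the SE length (default 0.5, so
focal amplicons are distinguished from megabase-scale gains; 0 recovers
any-overlap).  Cohort denominators come from a donor manifest, so donors
without any SV still count.  Each donor is counted at most once per SE.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .core import GenomicInterval, ParseError, ValidationError
from .consensus import CohortSeCatalog

__all__ = [
    "SvEvent",
    "RecurrenceResult",
    "duplication_recurrence",
    "recurrent_amplicon_ses",
    "read_sv_table",
    "write_sv_table",
    "read_donor_manifest",
    "write_donor_manifest",
]

SV_TYPES = ("DUP", "DEL", "INV", "TRA", "other")
DEFAULT_MIN_COVER = 0.5
DEFAULT_MIN_DONORS = 2


@dataclass(frozen=True)
class SvEvent:
    """A donor-labeled somatic structural variant."""

    donor_id: str
    cancer_type: str
    sv_type: str
    span: GenomicInterval | None  # None only for TRA

    def __post_init__(self) -> None:
        if not self.donor_id or not self.cancer_type:
            raise ValidationError("donor_id and cancer_type must be non-empty")
        if self.sv_type not in SV_TYPES:
            raise ValidationError(f"sv_type must be one of {SV_TYPES}")
        if self.sv_type != "TRA" and self.span is None:
            raise ValidationError(f"{self.sv_type} event needs a genomic span")


@dataclass(frozen=True)
class RecurrenceResult:
    n_donors_dup: int
    n_donors_total: int

    @property
    def frequency(self) -> float:
        return self.n_donors_dup / self.n_donors_total


def duplication_recurrence(
    se: GenomicInterval,
    events: Sequence[SvEvent],
    cohort: str,
    donors: Mapping[str, str],
    min_cover: float = DEFAULT_MIN_COVER,
) -> RecurrenceResult:
    """Fraction of cohort donors with a DUP covering >= min_cover of the SE.

    ``donors`` maps donor_id -> cancer_type (the manifest); the denominator
    is the number of manifest donors in ``cohort``.  Results are invariant
    to event order and to duplicated event records (donor-level dedup).
    """
    if not (0.0 <= min_cover <= 1.0):
        raise ValidationError("min_cover must lie in [0, 1]")
    total = sum(1 for ct in donors.values() if ct == cohort)
    if total == 0:
        raise ValidationError(f"no donors in cohort {cohort!r}")
    hit_donors: set[str] = set()
    need = min_cover * se.length
    for ev in events:
        if ev.cancer_type != cohort or ev.sv_type != "DUP" or ev.span is None:
            continue
        if se.overlap_bp(ev.span) >= need and se.overlap_bp(ev.span) > 0:
            hit_donors.add(ev.donor_id)
    return RecurrenceResult(n_donors_dup=len(hit_donors), n_donors_total=total)


def recurrent_amplicon_ses(
    catalog: CohortSeCatalog,
    events: Sequence[SvEvent],
    donors: Mapping[str, str],
    cohorts: Sequence[str],
    min_cover: float = DEFAULT_MIN_COVER,
    min_donors: int = DEFAULT_MIN_DONORS,
) -> pd.DataFrame:
    """Per (SE, cohort) duplication frequencies with a recurrence flag.

    The flag marks rows whose duplicated-donor count reaches ``min_donors``
    in that row's cohort.  Columns: se_id, chrom, start, end, cohort,
    n_donors_dup, n_donors_total, frequency, recurrent.
    """
    rows = []
    for entry in catalog.entries:
        for cohort in cohorts:
            res = duplication_recurrence(
                entry.span, events, cohort, donors, min_cover=min_cover
            )
            rows.append(
                {
                    "se_id": entry.se_id,
                    "chrom": entry.span.chrom,
                    "start": entry.span.start,
                    "end": entry.span.end,
                    "cohort": cohort,
                    "n_donors_dup": res.n_donors_dup,
                    "n_donors_total": res.n_donors_total,
                    "frequency": res.frequency,
                    "recurrent": res.n_donors_dup >= min_donors,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "se_id",
            "chrom",
            "start",
            "end",
            "cohort",
            "n_donors_dup",
            "n_donors_total",
            "frequency",
            "recurrent",
        ],
    )


def read_sv_table(path: str | Path) -> list[SvEvent]:
    """TSV: donor_id, cancer_type, sv_type, chrom, start, end (header optional)."""
    events: list[SvEvent] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#") or line.startswith("donor_id\t"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(f"{path}:{lineno}: expected 6 columns")
            donor, ctype, svtype = fields[0], fields[1], fields[2]
            span = None
            if svtype != "TRA":
                try:
                    span = GenomicInterval(fields[3], int(fields[4]), int(fields[5]))
                except (ValueError, ValidationError) as exc:
                    raise ParseError(f"{path}:{lineno}: {exc}") from exc
            events.append(SvEvent(donor, ctype, svtype, span))
    return events


def write_sv_table(events: Sequence[SvEvent], path: str | Path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("donor_id\tcancer_type\tsv_type\tchrom\tstart\tend\n")
        for ev in events:
            if ev.span is None:
                fh.write(f"{ev.donor_id}\t{ev.cancer_type}\t{ev.sv_type}\t.\t.\t.\n")
            else:
                fh.write(
                    f"{ev.donor_id}\t{ev.cancer_type}\t{ev.sv_type}\t"
                    f"{ev.span.chrom}\t{ev.span.start}\t{ev.span.end}\n"
                )


def read_donor_manifest(path: str | Path) -> dict[str, str]:
    donors: dict[str, str] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#") or line.startswith("donor_id\t"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns")
            donors[fields[0]] = fields[1]
    return donors


def write_donor_manifest(donors: Mapping[str, str], path: str | Path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("donor_id\tcancer_type\n")
        for donor in sorted(donors):
            fh.write(f"{donor}\t{donors[donor]}\n")
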