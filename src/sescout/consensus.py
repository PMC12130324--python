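"""Cohort-level SE catalogs, cross-cohort sharing and lineage specificity.

Per-sample SE calls are merged into a cohort catalog by transitive >=1 bp
overlap (SE identity across samples); catalogs from two cohorts are then
intersected into a Venn structure (shared / A-only / B-only), and a presence
matrix over many cancer-type cohorts yields a lineage-specificity score per
merged SE.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import GenomicInterval, ValidationError, overlap_pairs

__all__ = [
    "MergedSe",
    "CohortSeCatalog",
    "SharedResult",
    "merge_cohort",
    "shared_ses",
    "presence_matrix",
    "lineage_specificity",
]


@dataclass(frozen=True)
class MergedSe:
    """A cohort-merged SE footprint with its supporting samples."""

    span: GenomicInterval
    support: int
    members: tuple[str, ...]

    @property
    def se_id(self) -> str:
        return str(self.span)


@dataclass
class CohortSeCatalog:
    cohort_id: str
    entries: list[MergedSe]
    build: str = "synthetic"

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def spans(self) -> list[GenomicInterval]:
        return [e.span for e in self.entries]


def merge_cohort(
    per_sample: Mapping[str, Sequence[GenomicInterval]],
    min_support: int = 1,
    cohort_id: str = "cohort",
    build: str = "synthetic",
) -> CohortSeCatalog:
    """Merge per-sample SE intervals into a non-overlapping cohort catalog.

    Merged footprint = union of transitively overlapping (>=1 bp) SE
    intervals across samples; support counts distinct contributing samples.
    Entries with support below ``min_support`` are dropped.  The result is
    invariant to sample input order.
    """
    if not per_sample:
        raise ValidationError("merge_cohort needs >= 1 sample")
    tagged: list[tuple[GenomicInterval, str]] = []
    for sample_id in sorted(per_sample):
        for iv in per_sample[sample_id]:
            tagged.append((iv, sample_id))
    tagged.sort(key=lambda t: (t[0].chrom, t[0].start, t[0].end, t[1]))

    entries: list[MergedSe] = []
    cur_span: GenomicInterval | None = None
    cur_members: set[str] = set()

    def close() -> None:
        if cur_span is not None:
            entries.append(
                MergedSe(
                    span=cur_span,
                    support=len(cur_members),
                    members=tuple(sorted(cur_members)),
                )
            )

    for iv, sample_id in tagged:
        if (
            cur_span is not None
            and iv.chrom == cur_span.chrom
            and iv.start < cur_span.end
        ):
            cur_span = GenomicInterval(
                cur_span.chrom, cur_span.start, max(cur_span.end, iv.end)
            )
            cur_members.add(sample_id)
        else:
            close()
            cur_span = GenomicInterval(iv.chrom, iv.start, iv.end)
            cur_members = {sample_id}
    close()
    entries = [e for e in entries if e.support >= min_support]
    return CohortSeCatalog(cohort_id=cohort_id, entries=entries, build=build)


@dataclass
class SharedResult:
    """Venn structure between two catalogs: shared pairs plus exclusives."""

    pairs: list[tuple[int, int, int]]  # (index in A, index in B, overlap bp)
    a_only: list[int]
    b_only: list[int]

    @property
    def n_shared_a(self) -> int:
        return len({i for i, _, _ in self.pairs})

    @property
    def n_shared_b(self) -> int:
        return len({j for _, j, _ in self.pairs})


def shared_ses(
    catalog_a: CohortSeCatalog,
    catalog_b: CohortSeCatalog,
    min_overlap_fraction: float = 0.0,
) -> SharedResult:
    """Match SEs across two catalogs by overlap.

    A pair is shared iff overlap >= 1 bp and overlap / min(len_a, len_b)
    >= ``min_overlap_fraction``.  Exclusives partition each catalog:
    |a_only| + |A entries in pairs| = |catalog_a| (and likewise for B).
    """
    if catalog_a.build != catalog_b.build:
        raise ValidationError(
            f"catalog build mismatch: {catalog_a.build!r} vs {catalog_b.build!r}"
        )
    if not (0.0 <= min_overlap_fraction <= 1.0):
        raise ValidationError("min_overlap_fraction must lie in [0, 1]")
    raw = overlap_pairs(catalog_a.spans, catalog_b.spans, min_bp=1)
    pairs = [
        (i, j, bp)
        for i, j, bp in raw
        if bp / min(catalog_a.entries[i].span.length, catalog_b.entries[j].span.length)
        >= min_overlap_fraction
    ]
    in_a = {i for i, _, _ in pairs}
    in_b = {j for _, j, _ in pairs}
    a_only = [i for i in range(len(catalog_a)) if i not in in_a]
    b_only = [j for j in range(len(catalog_b)) if j not in in_b]
    return SharedResult(pairs=pairs, a_only=a_only, b_only=b_only)


def presence_matrix(
    catalog: CohortSeCatalog,
    cohort_samples: Mapping[str, Mapping[str, Sequence[GenomicInterval]]],
) -> pd.DataFrame:
    """Fraction of each cohort's samples carrying each merged SE.

    A sample carries an SE iff any of its SE calls overlaps (>= 1 bp) the
    merged footprint.  Rows are SE ids, columns cohort ids, cells in [0, 1].
    """
    spans = catalog.spans
    data: dict[str, list[float]] = {}
    for cohort_id in sorted(cohort_samples):
        samples = cohort_samples[cohort_id]
        if not samples:
            raise ValidationError(f"cohort {cohort_id!r} has no samples")
        counts = np.zeros(len(spans), dtype=int)
        for sample_id in sorted(samples):
            hit = {i for i, _, _ in overlap_pairs(spans, samples[sample_id], min_bp=1)}
            for i in hit:
                counts[i] += 1
        data[cohort_id] = list(counts / len(samples))
    return pd.DataFrame(data, index=[e.se_id for e in catalog.entries])


def lineage_specificity(
    presence: pd.DataFrame, target_cohorts: set[str] | Sequence[str]
) -> pd.Series:
    """Mean presence over target cohorts minus mean presence elsewhere.

    The score lies in [-1, 1]; it is 1 iff the SE is present in every target
    cohort sample and absent from all others.
    """
    targets = set(target_cohorts)
    cols = set(presence.columns)
    if not targets or not targets.issubset(cols) or targets == cols:
        raise ValidationError(
            "target cohorts must be a non-empty proper subset of matrix columns"
        )
    others = sorted(cols - targets)
    score = presence[sorted(targets)].mean(axis=1) - presence[others].mean(axis=1)
    score.name = "specificity"
    return score
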