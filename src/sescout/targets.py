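"""Target-gene nomination and expression integration for super-enhancers.

Genes are nominated either by chromatin loops (a significant HiChIP loop,
FDR strictly below threshold, with one anchor on the SE and the other on the
gene's promoter window) or by nearest-TSS assignment; nominated genes are
then categorized by interaction x expression, and ChIP-bound gene sets are
intersected with differential expression to yield direct-target lists.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .core import GeneModel, GenomicInterval, Loop, ValidationError, overlap_pairs

__all__ = [
    "DeRecord",
    "GeneCategory",
    "SeGenePair",
    "NearestAssignment",
    "promoter_windows",
    "loop_assign",
    "nearest_gene",
    "categorize_genes",
    "direct_targets",
    "read_de_table",
    "write_de_table",
]

DEFAULT_PROMOTER_FLANK = 2_500
DEFAULT_FDR_MAX = 0.05

CATEGORY_LABELS = ("interaction+up", "interaction only", "up only", "neither")


@dataclass(frozen=True)
class DeRecord:
    """One row of a differential-expression table."""

    gene_id: str
    log2fc: float
    fdr: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.fdr <= 1.0):
            raise ValidationError(f"DE FDR must lie in [0, 1], got {self.fdr}")
        if not math.isfinite(self.log2fc):
            raise ValidationError("log2FC must be finite")


@dataclass(frozen=True)
class GeneCategory:
    gene_id: str
    has_interaction: bool
    is_upregulated: bool | None  # None = gene absent from the DE table
    category: str

    @property
    def measured(self) -> bool:
        return self.is_upregulated is not None


@dataclass(frozen=True)
class SeGenePair:
    se_index: int
    gene_id: str
    best_fdr: float
    pet_count: int


@dataclass(frozen=True)
class NearestAssignment:
    site_index: int
    gene_id: str | None
    distance: int | None
    tie: bool


def promoter_windows(
    genes: Sequence[GeneModel], flank: int = DEFAULT_PROMOTER_FLANK
) -> dict[str, GenomicInterval]:
    """TSS +/- flank per gene, strand-aware, clipped at 0."""
    windows: dict[str, GenomicInterval] = {}
    for g in genes:
        pos = g.tss_pos
        windows[g.gene_id] = GenomicInterval(
            g.body.chrom, max(0, pos - flank), pos + flank, g.body.strand
        )
    return windows


def loop_assign(
    ses: Sequence[GenomicInterval],
    loops: Sequence[Loop],
    promoters: Mapping[str, GenomicInterval],
    fdr_max: float = DEFAULT_FDR_MAX,
) -> list[SeGenePair]:
    """Link SEs to genes through significant loops (FDR strictly < fdr_max).

    A pair is emitted iff some qualifying loop has one anchor overlapping the
    SE and the other overlapping the gene's promoter window (either
    orientation).  ``best_fdr`` is the minimum over qualifying loops and
    ``pet_count`` the PET count of that best loop.  Output is monotone in
    ``fdr_max``: relaxing the threshold never removes a pair.
    """
    gene_ids = sorted(promoters)
    prom_spans = [promoters[g] for g in gene_ids]
    sig = [lp for lp in loops if lp.fdr < fdr_max]
    a1 = [lp.anchor1 for lp in sig]
    a2 = [lp.anchor2 for lp in sig]

    se_hits_1 = _group(overlap_pairs(a1, ses))  # loop idx -> SE indices
    se_hits_2 = _group(overlap_pairs(a2, ses))
    pr_hits_1 = _group(overlap_pairs(a1, prom_spans))
    pr_hits_2 = _group(overlap_pairs(a2, prom_spans))

    best: dict[tuple[int, str], tuple[float, int]] = {}
    for k, lp in enumerate(sig):
        for se_hits, pr_hits in ((se_hits_1, pr_hits_2), (se_hits_2, pr_hits_1)):
            for si in se_hits.get(k, ()):
                for gj in pr_hits.get(k, ()):
                    key = (si, gene_ids[gj])
                    cand = (lp.fdr, lp.pet_count)
                    cur = best.get(key)
                    if cur is None or cand[0] < cur[0] or (
                        cand[0] == cur[0] and cand[1] > cur[1]
                    ):
                        best[key] = cand
    return [
        SeGenePair(se_index=si, gene_id=g, best_fdr=f, pet_count=p)
        for (si, g), (f, p) in sorted(best.items())
    ]


def _group(pairs: Iterable[tuple[int, int, int]]) -> dict[int, list[int]]:
    out: dict[int, list[int]] = {}
    for i, j, _ in pairs:
        out.setdefault(i, []).append(j)
    return out


def nearest_gene(
    sites: Sequence[GenomicInterval], genes: Sequence[GeneModel]
) -> list[NearestAssignment]:
    """Assign each site to the gene whose TSS is closest to the site midpoint.

    Sites on chromosomes without genes come back unassigned.  Exact-distance
    ties break toward the lexicographically smaller gene_id and are flagged.
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.body.chrom, []).append(g)
    out: list[NearestAssignment] = []
    for idx, site in enumerate(sites):
        cands = by_chrom.get(site.chrom)
        if not cands:
            out.append(NearestAssignment(idx, None, None, False))
            continue
        mid = site.midpoint
        ranked = sorted(cands, key=lambda g: (abs(g.tss_pos - mid), g.gene_id))
        best = ranked[0]
        dist = abs(best.tss_pos - mid)
        tie = len(ranked) > 1 and abs(ranked[1].tss_pos - mid) == dist
        out.append(NearestAssignment(idx, best.gene_id, dist, tie))
    return out


def categorize_genes(
    se_genes: Iterable[str],
    loop_pairs: Sequence[SeGenePair],
    de: Sequence[DeRecord],
    fc_min: float = 0.0,
    fdr_max: float = DEFAULT_FDR_MAX,
) -> tuple[list[GeneCategory], Counter]:
    """Categorize SE-nominated genes by interaction x upregulation.

    ``has_interaction`` iff the gene appears in ``loop_pairs``;
    ``is_upregulated`` iff log2FC > fc_min and FDR < fdr_max.  Genes absent
    from the DE table are labeled ``unmeasured`` and excluded from the
    four-category counts (never silently "not upregulated").
    """
    interacting = {p.gene_id for p in loop_pairs}
    de_map = {r.gene_id: r for r in de}
    cats: list[GeneCategory] = []
    counts: Counter = Counter({label: 0 for label in CATEGORY_LABELS})
    for gene_id in sorted(set(se_genes)):
        has_int = gene_id in interacting
        rec = de_map.get(gene_id)
        if rec is None:
            cats.append(GeneCategory(gene_id, has_int, None, "unmeasured"))
            continue
        up = rec.log2fc > fc_min and rec.fdr < fdr_max
        if has_int and up:
            label = "interaction+up"
        elif has_int:
            label = "interaction only"
        elif up:
            label = "up only"
        else:
            label = "neither"
        counts[label] += 1
        cats.append(GeneCategory(gene_id, has_int, up, label))
    return cats, counts


def direct_targets(
    chip_genes: Iterable[str],
    de: Sequence[DeRecord],
    fdr_max: float = DEFAULT_FDR_MAX,
) -> tuple[set[str], set[str]]:
    """Intersect a ChIP-bound gene set with significant differential expression.

    Returns ``(down_targets, up_targets)``: bound genes whose expression
    changes significantly (FDR < fdr_max) downward or upward.  The two sets
    are disjoint by construction (log2FC of exactly 0 is in neither).
    """
    chip = set(chip_genes)
    down = {r.gene_id for r in de if r.gene_id in chip and r.log2fc < 0 and r.fdr < fdr_max}
    up = {r.gene_id for r in de if r.gene_id in chip and r.log2fc > 0 and r.fdr < fdr_max}
    return down, up


def read_de_table(path: str | Path) -> list[DeRecord]:
    """TSV with columns gene_id, log2fc, fdr (header optional)."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    cols = [c.lower() for c in df.columns]
    if "gene_id" not in cols:  # headerless
        df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "log2fc", "fdr"])
    else:
        df.columns = cols
    return [
        DeRecord(str(r.gene_id), float(r.log2fc), float(r.fdr))
        for r in df.itertuples(index=False)
    ]


def write_de_table(records: Sequence[DeRecord], path: str | Path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("gene_id\tlog2fc\tfdr\n")
        for r in records:
            fh.write(f"{r.gene_id}\t{r.log2fc:.6g}\t{r.fdr:.6g}\n")
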