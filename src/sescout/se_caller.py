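"""ROSE-style super-enhancer calling.

Enhancer peaks are stitched into candidate regions when their genomic gaps
fall below a distance threshold (default 12.5 kb), scored by aggregate
H3K27ac signal mass (optionally input-subtracted), ranked, and split into
super-enhancers vs typical enhancers at the hockey-stick inflection: the
point of the rank-vs-signal curve, scaled to the unit square, where the
tangent slope passes 1.  On discrete data the cutoff is the standard
surrogate argmin(y - x); ties break toward the larger index (fewer,
stronger SEs), and the top-ranked point itself can never be the cutoff, so
the SE set is never empty.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import (
    GenomicInterval,
    SignalTrack,
    ValidationError,
    aggregate_signal,
    sort_intervals,
)

__all__ = [
    "DegenerateCurveError",
    "StitchedRegion",
    "HockeyStick",
    "SampleSeCalls",
    "merge_overlapping",
    "stitch_peaks",
    "hockey_stick_cutoff",
    "call_sample_ses",
]

DEFAULT_STITCH_DISTANCE = 12_500
DEFAULT_TSS_EXCLUSION = 2_500


class DegenerateCurveError(ValueError):
    """All region signals are equal; no inflection exists.  Skip the sample."""


@dataclass
class StitchedRegion:
    """A stitched candidate enhancer region for one sample."""

    span: GenomicInterval
    constituents: tuple[GenomicInterval, ...]
    signal: float = float("nan")
    sample_id: str | None = None
    promoter_proximal: bool = False

    @property
    def n_constituents(self) -> int:
        return len(self.constituents)


@dataclass
class HockeyStick:
    """Ranked enhancer curve with the inflection cutoff.

    ``regions`` are sorted by ascending signal; ``x`` is the scaled rank
    (i-1)/(n-1) and ``y`` the min-max scaled signal, both in [0, 1].
    Regions with signal strictly above ``cutoff_signal`` are super-enhancers.
    """

    regions: list[StitchedRegion]
    x: np.ndarray
    y: np.ndarray
    cutoff_index: int
    cutoff_signal: float

    @property
    def labels(self) -> list[str]:
        return [
            "SE" if r.signal > self.cutoff_signal else "typical" for r in self.regions
        ]

    @property
    def superenhancers(self) -> list[StitchedRegion]:
        return [r for r in self.regions if r.signal > self.cutoff_signal]

    @property
    def typical(self) -> list[StitchedRegion]:
        return [r for r in self.regions if r.signal <= self.cutoff_signal]


@dataclass
class SampleSeCalls:
    sample_id: str | None
    superenhancers: list[StitchedRegion]
    typical: list[StitchedRegion]
    hockey: HockeyStick


def merge_overlapping(peaks: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Union of overlapping (>=1 bp) intervals; half-open abutment not merged."""
    merged: list[GenomicInterval] = []
    for iv in sort_intervals(peaks):
        if merged and merged[-1].chrom == iv.chrom and iv.start < merged[-1].end:
            prev = merged[-1]
            merged[-1] = GenomicInterval(prev.chrom, prev.start, max(prev.end, iv.end))
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return merged


def stitch_peaks(
    peaks: Sequence[GenomicInterval],
    stitch_distance: int = DEFAULT_STITCH_DISTANCE,
    tss: Sequence[GenomicInterval] = (),
    tss_exclusion: int = DEFAULT_TSS_EXCLUSION,
    sample_id: str | None = None,
) -> list[StitchedRegion]:
    """Stitch peaks whose consecutive gaps are <= ``stitch_distance``.

    Overlapping peaks are merged first.  A peak whose center lies within
    ``tss_exclusion`` bp of a TSS is withheld from stitching and returned as
    its own region flagged ``promoter_proximal`` (it still participates in
    ranking downstream).  Gaps between distinct output regions are strictly
    greater than ``stitch_distance``.
    """
    if stitch_distance < 0:
        raise ValidationError("stitch_distance must be >= 0")
    if tss_exclusion < 0:
        raise ValidationError("tss_exclusion must be >= 0")
    merged = merge_overlapping(peaks)
    if not merged:
        return []

    tmp: dict[str, list[int]] = {}
    for t in tss:
        tmp.setdefault(t.chrom, []).append(t.start)
    tss_by_chrom = {c: np.sort(np.array(p, dtype=np.int64)) for c, p in tmp.items()}

    def near_tss(iv: GenomicInterval) -> bool:
        pos = tss_by_chrom.get(iv.chrom)
        if pos is None or len(pos) == 0:
            return False
        center = iv.midpoint
        k = int(np.searchsorted(pos, center))
        dists = []
        if k < len(pos):
            dists.append(abs(int(pos[k]) - center))
        if k > 0:
            dists.append(abs(int(pos[k - 1]) - center))
        return min(dists) <= tss_exclusion

    proximal = [p for p in merged if near_tss(p)]
    stitchable = [p for p in merged if not near_tss(p)]

    regions: list[StitchedRegion] = []
    group: list[GenomicInterval] = []
    for iv in stitchable:
        if group and iv.chrom == group[-1].chrom and iv.start - group[-1].end <= stitch_distance:
            group.append(iv)
        else:
            if group:
                regions.append(_close_group(group, sample_id))
            group = [iv]
    if group:
        regions.append(_close_group(group, sample_id))

    for p in proximal:
        regions.append(
            StitchedRegion(
                span=GenomicInterval(p.chrom, p.start, p.end),
                constituents=(p,),
                sample_id=sample_id,
                promoter_proximal=True,
            )
        )
    regions.sort(key=lambda r: (r.span.chrom, r.span.start, r.span.end))
    return regions


def _close_group(group: list[GenomicInterval], sample_id: str | None) -> StitchedRegion:
    return StitchedRegion(
        span=GenomicInterval(group[0].chrom, group[0].start, group[-1].end),
        constituents=tuple(group),
        sample_id=sample_id,
    )


def hockey_stick_cutoff(regions: Sequence[StitchedRegion]) -> HockeyStick:
    """Rank regions by signal and locate the hockey-stick inflection.

    With regions sorted ascending, x_i = (i-1)/(n-1) and
    y_i = (s_i - s_min)/(s_max - s_min); the cutoff index is
    argmin(y - x) over i = 1..n-1 (the top point is excluded, so at least
    one region is always labeled SE), ties broken toward the larger index.
    """
    if len(regions) < 2:
        raise ValidationError("hockey stick needs >= 2 regions")
    ordered = sorted(
        regions, key=lambda r: (r.signal, r.span.chrom, r.span.start, r.span.end)
    )
    signals = np.array([r.signal for r in ordered], dtype=float)
    if not np.all(np.isfinite(signals)):
        raise ValidationError("region signals must be finite")
    smin, smax = float(signals[0]), float(signals[-1])
    if smax == smin:
        raise DegenerateCurveError(
            "all region signals are equal; no hockey-stick inflection — skip sample"
        )
    n = len(ordered)
    x = np.arange(n, dtype=float) / (n - 1)
    y = (signals - smin) / (smax - smin)
    diff = (y - x)[:-1]  # the top point can never be the cutoff
    cutoff_index = int(len(diff) - 1 - np.argmin(diff[::-1]))  # ties -> larger index
    return HockeyStick(
        regions=list(ordered),
        x=x,
        y=y,
        cutoff_index=cutoff_index,
        cutoff_signal=float(signals[cutoff_index]),
    )


def call_sample_ses(
    peaks: Sequence[GenomicInterval],
    signal: SignalTrack,
    control: SignalTrack | None = None,
    *,
    stitch_distance: int = DEFAULT_STITCH_DISTANCE,
    tss: Sequence[GenomicInterval] = (),
    tss_exclusion: int = DEFAULT_TSS_EXCLUSION,
    sample_id: str | None = None,
) -> SampleSeCalls:
    """Stitch, score and classify one sample's enhancer landscape.

    Region signal is the aggregate signal mass over the stitched span; when
    an input-DNA control track is supplied its mass is subtracted and the
    result floored at 0 (negative enrichment is treated as no enrichment).
    """
    regions = stitch_peaks(
        peaks,
        stitch_distance=stitch_distance,
        tss=tss,
        tss_exclusion=tss_exclusion,
        sample_id=sample_id,
    )
    for r in regions:
        s = aggregate_signal(r.span, signal)
        if control is not None:
            s = max(0.0, s - aggregate_signal(r.span, control))
        r.signal = s
    hockey = hockey_stick_cutoff(regions)
    return SampleSeCalls(
        sample_id=sample_id,
        superenhancers=hockey.superenhancers,
        typical=hockey.typical,
        hockey=hockey,
    )
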