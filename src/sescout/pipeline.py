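"""Single-command pipeline: SE catalogs -> sharing -> targets -> recurrence.

Chains super-enhancer calling, cohort consensus, loop-based target
nomination with expression integration, duplication recurrence, dependency
normalization and motif scanning from one config, with stage-level logging
of record counts (so filter attrition is auditable) and a final ``report.tsv``
ranking merged SEs lexicographically by (shared across lineage cohorts,
loop-linked upregulated target, recurrent duplication, lineage specificity).
Reruns on identical inputs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml
from Bio import SeqIO

from . import consensus as cns
from . import dependency as dep
from . import motifs as mot
from . import sv as svmod
from . import targets as tgt
from .core import (
    GenomicInterval,
    SignalTrack,
    ValidationError,
    read_bed,
    read_bedpe_loops,
    read_gene_table,
    write_bed,
    BedInterval,
)
from .se_caller import (
    DEFAULT_STITCH_DISTANCE,
    DEFAULT_TSS_EXCLUSION,
    call_sample_ses,
)
from .simulate import DatasetBundle

__all__ = [
    "PipelineConfig",
    "SampleInput",
    "CohortInput",
    "PipelineStageError",
    "PipelineResult",
    "run_pipeline",
]

log = logging.getLogger("sescout.pipeline")


class PipelineStageError(RuntimeError):
    """A stage failed; the message names the stage and the offending input."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class SampleInput:
    sample_id: str
    peaks: str
    signal: str
    control: str | None = None


@dataclass
class CohortInput:
    samples: list[SampleInput]
    loops: str | None = None
    de: str | None = None


@dataclass
class PipelineConfig:
    """All inputs and module parameters for one pipeline run."""

    genes: str
    cohorts: dict[str, CohortInput]
    outdir: str
    target_cohorts: list[str] = field(default_factory=list)
    sv: str | None = None
    donors: str | None = None
    sv_cohorts: list[str] = field(default_factory=list)
    focal_sv_cohort: str | None = None
    gene_effect: str | None = None
    essential: str | None = None
    nonessential: str | None = None
    expression: str | None = None
    fasta: str | None = None
    pwm: str | None = None
    # parameters
    stitch_distance: int = DEFAULT_STITCH_DISTANCE
    tss_exclusion: int = DEFAULT_TSS_EXCLUSION
    promoter_flank: int = tgt.DEFAULT_PROMOTER_FLANK
    fdr_max: float = tgt.DEFAULT_FDR_MAX
    fc_min: float = 0.0
    min_support: int = 1
    min_overlap_fraction: float = 0.0
    min_cover: float = svmod.DEFAULT_MIN_COVER
    min_donors: int = svmod.DEFAULT_MIN_DONORS
    dependency_cutoff: float = dep.DEFAULT_DEPENDENCY_CUTOFF
    p_max: float = mot.DEFAULT_P_MAX
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.target_cohorts:
            self.target_cohorts = [
                c for c, ci in self.cohorts.items() if ci.loops is not None
            ] or list(self.cohorts)
        if self.focal_sv_cohort is None and self.sv_cohorts:
            self.focal_sv_cohort = self.sv_cohorts[0]

    def validate(self) -> None:
        missing = [
            p
            for p in self._all_paths()
            if p is not None and not Path(p).exists()
        ]
        if missing:
            raise ValidationError(f"missing input path(s): {missing}")
        for name, value, lo, hi in (
            ("fdr_max", self.fdr_max, 0.0, 1.0),
            ("min_cover", self.min_cover, 0.0, 1.0),
            ("min_overlap_fraction", self.min_overlap_fraction, 0.0, 1.0),
            ("p_max", self.p_max, 0.0, 1.0),
        ):
            if not (lo <= value <= hi):
                raise ValidationError(f"{name} must lie in [{lo}, {hi}]")

    def _all_paths(self):
        yield self.genes
        for ci in self.cohorts.values():
            for s in ci.samples:
                yield s.peaks
                yield s.signal
                yield s.control
            yield ci.loops
            yield ci.de
        for p in (
            self.sv,
            self.donors,
            self.gene_effect,
            self.essential,
            self.nonessential,
            self.expression,
            self.fasta,
            self.pwm,
        ):
            yield p

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "rt", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        cohorts = {
            name: CohortInput(
                samples=[SampleInput(**s) for s in spec.get("samples", [])],
                loops=spec.get("loops"),
                de=spec.get("de"),
            )
            for name, spec in raw.pop("cohorts").items()
        }
        return cls(cohorts=cohorts, **raw)

    @classmethod
    def from_bundle(cls, bundle: DatasetBundle, outdir: str | Path, **overrides) -> "PipelineConfig":
        """Wire a synthetic dataset bundle straight into a pipeline config."""
        cohorts = {
            cohort: CohortInput(
                samples=[
                    SampleInput(s.sample_id, str(s.peaks), str(s.signal))
                    for s in files
                ],
                loops=str(bundle.loops[cohort]) if cohort in bundle.loops else None,
                de=str(bundle.de[cohort]) if cohort in bundle.de else None,
            )
            for cohort, files in bundle.samples.items()
        }
        donors = svmod.read_donor_manifest(bundle.donors)
        sv_cohorts = sorted(set(donors.values()))
        return cls(
            genes=str(bundle.genes),
            cohorts=cohorts,
            outdir=str(outdir),
            sv=str(bundle.sv),
            donors=str(bundle.donors),
            sv_cohorts=sv_cohorts,
            focal_sv_cohort=sv_cohorts[0] if sv_cohorts else None,
            gene_effect=str(bundle.gene_effect),
            essential=str(bundle.essential),
            nonessential=str(bundle.nonessential),
            expression=str(bundle.expression),
            fasta=str(bundle.fasta),
            pwm=str(bundle.pwm),
            **overrides,
        )


@dataclass
class PipelineResult:
    report: pd.DataFrame
    report_path: Path
    union_catalog: cns.CohortSeCatalog
    cohort_catalogs: dict[str, cns.CohortSeCatalog]
    per_sample_ses: dict[str, dict[str, list[GenomicInterval]]]
    outputs: dict[str, Path]


def _csv(df: pd.DataFrame, path: Path, **kw) -> None:
    df.to_csv(path, sep="\t", float_format="%.6g", **kw)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    cfg = config
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "se_calls").mkdir(exist_ok=True)
    outputs: dict[str, Path] = {}

    # ---- stage 1: SE calling -------------------------------------------------
    stage = "se_caller"
    try:
        genes = read_gene_table(cfg.genes)
        tss = [g.tss for g in genes]
        per_sample_ses: dict[str, dict[str, list[GenomicInterval]]] = {}
        for cohort in sorted(cfg.cohorts):
            per_sample_ses[cohort] = {}
            for s in cfg.cohorts[cohort].samples:
                peaks = read_bed(s.peaks)
                signal = SignalTrack.from_bedgraph(s.signal)
                control = (
                    SignalTrack.from_bedgraph(s.control) if s.control else None
                )
                calls = call_sample_ses(
                    peaks,
                    signal,
                    control,
                    stitch_distance=cfg.stitch_distance,
                    tss=tss,
                    tss_exclusion=cfg.tss_exclusion,
                    sample_id=s.sample_id,
                )
                ses = [r.span for r in calls.superenhancers]
                per_sample_ses[cohort][s.sample_id] = ses
                _write_sample_outputs(outdir / "se_calls", s.sample_id, calls)
                log.info(
                    "[se_caller] %s/%s: %d peaks -> %d regions -> %d SEs",
                    cohort, s.sample_id, len(peaks), len(calls.hockey.regions), len(ses),
                )
    except Exception as exc:  # noqa: BLE001 - annotate stage and re-raise
        raise PipelineStageError(stage, str(exc)) from exc

    # ---- stage 2: cohort consensus ------------------------------------------
    stage = "cohort_consensus"
    try:
        cohort_catalogs = {
            cohort: cns.merge_cohort(
                per_sample_ses[cohort], min_support=cfg.min_support, cohort_id=cohort
            )
            for cohort in sorted(cfg.cohorts)
        }
        for cohort, cat in cohort_catalogs.items():
            path = outdir / f"{cohort}.merged_se.bed"
            write_bed(
                [
                    BedInterval(e.span.chrom, e.span.start, e.span.end, name=e.se_id, score=float(e.support))
                    for e in cat.entries
                ],
                path,
            )
            outputs[f"merged_se_{cohort}"] = path
            log.info("[cohort_consensus] %s: %d merged SEs", cohort, len(cat))

        union_samples: dict[str, list[GenomicInterval]] = {}
        for cohort in cfg.target_cohorts:
            union_samples.update(per_sample_ses[cohort])
        union = cns.merge_cohort(union_samples, min_support=cfg.min_support, cohort_id="union")

        venn_rows = []
        tc = cfg.target_cohorts
        if len(tc) >= 2:
            shared = cns.shared_ses(
                cohort_catalogs[tc[0]], cohort_catalogs[tc[1]], cfg.min_overlap_fraction
            )
            venn_rows.append(
                {
                    "cohort_a": tc[0],
                    "cohort_b": tc[1],
                    "shared_a": shared.n_shared_a,
                    "shared_b": shared.n_shared_b,
                    "a_only": len(shared.a_only),
                    "b_only": len(shared.b_only),
                }
            )
        venn_path = outdir / "venn.tsv"
        _csv(pd.DataFrame(venn_rows), venn_path, index=False)
        outputs["venn"] = venn_path

        presence = cns.presence_matrix(
            union, {c: per_sample_ses[c] for c in sorted(cfg.cohorts)}
        )
        _csv(presence, outdir / "presence.tsv", index_label="se_id")
        outputs["presence"] = outdir / "presence.tsv"
        non_target = set(cfg.cohorts) - set(cfg.target_cohorts)
        specificity = None
        if non_target:
            specificity = cns.lineage_specificity(presence, set(cfg.target_cohorts))
            _csv(specificity.to_frame(), outdir / "specificity.tsv", index_label="se_id")
            outputs["specificity"] = outdir / "specificity.tsv"
    except PipelineStageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError(stage, str(exc)) from exc

    # ---- stage 3: target assignment -----------------------------------------
    stage = "target_assignment"
    interaction_available = any(
        cfg.cohorts[c].loops is not None for c in cfg.target_cohorts
    )
    try:
        promoters = tgt.promoter_windows(genes, flank=cfg.promoter_flank)
        union_spans = union.spans
        pair_rows = []
        cat_rows = []
        looped_up_se: set[int] = set()
        for cohort in cfg.target_cohorts:
            ci = cfg.cohorts[cohort]
            if ci.loops is not None:
                loops = read_bedpe_loops(ci.loops)
                pairs = tgt.loop_assign(union_spans, loops, promoters, fdr_max=cfg.fdr_max)
                nominated = {p.gene_id for p in pairs}
            else:
                loops, pairs = [], []
                near = tgt.nearest_gene(union_spans, genes)
                nominated = {a.gene_id for a in near if a.gene_id is not None}
            de_records = tgt.read_de_table(ci.de) if ci.de else []
            cats, counts = tgt.categorize_genes(
                nominated, pairs, de_records, fc_min=cfg.fc_min, fdr_max=cfg.fdr_max
            )
            up_genes = {
                c.gene_id for c in cats if c.category in ("interaction+up", "up only")
            }
            for p in pairs:
                pair_rows.append(
                    {
                        "cohort": cohort,
                        "se_id": union.entries[p.se_index].se_id,
                        "se_index": p.se_index,
                        "gene_id": p.gene_id,
                        "best_fdr": p.best_fdr,
                        "pet_count": p.pet_count,
                    }
                )
                if p.gene_id in up_genes:
                    looped_up_se.add(p.se_index)
            for c in cats:
                cat_rows.append(
                    {
                        "cohort": cohort,
                        "gene_id": c.gene_id,
                        "has_interaction": c.has_interaction,
                        "is_upregulated": "" if c.is_upregulated is None else c.is_upregulated,
                        "category": c.category,
                    }
                )
            log.info(
                "[target_assignment] %s: %d loops -> %d SE-gene pairs, categories %s",
                cohort, len(loops), len(pairs), dict(counts),
            )
        _csv(pd.DataFrame(pair_rows), outdir / "se_gene_pairs.tsv", index=False)
        _csv(pd.DataFrame(cat_rows), outdir / "gene_categories.tsv", index=False)
        outputs["se_gene_pairs"] = outdir / "se_gene_pairs.tsv"
        outputs["gene_categories"] = outdir / "gene_categories.tsv"
    except PipelineStageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError(stage, str(exc)) from exc

    # ---- stage 4: SV recurrence ---------------------------------------------
    stage = "sv_recurrence"
    recurrence = None
    recurrent_se_ids: set[str] = set()
    try:
        if cfg.sv and cfg.donors:
            events = svmod.read_sv_table(cfg.sv)
            donors = svmod.read_donor_manifest(cfg.donors)
            sv_cohorts = cfg.sv_cohorts or sorted(set(donors.values()))
            recurrence = svmod.recurrent_amplicon_ses(
                union,
                events,
                donors,
                sv_cohorts,
                min_cover=cfg.min_cover,
                min_donors=cfg.min_donors,
            )
            _csv(recurrence, outdir / "amplicon_recurrence.tsv", index=False)
            outputs["amplicon_recurrence"] = outdir / "amplicon_recurrence.tsv"
            focal = cfg.focal_sv_cohort
            mask = (recurrence["cohort"] == focal) & recurrence["recurrent"]
            recurrent_se_ids = set(recurrence.loc[mask, "se_id"])
            log.info(
                "[sv_recurrence] %d events, %d donors -> %d recurrent SEs in %s",
                len(events), len(donors), len(recurrent_se_ids), focal,
            )
    except PipelineStageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError(stage, str(exc)) from exc

    # ---- stage 5: dependency -------------------------------------------------
    stage = "dependency"
    try:
        if cfg.gene_effect and cfg.essential and cfg.nonessential:
            raw = dep.read_gene_effect(cfg.gene_effect, cfg.essential, cfg.nonessential)
            normalized = dep.normalize_gene_effect(raw)
            dep.write_gene_effect(normalized, outdir / "dependency_normalized.tsv")
            calls_df = dep.call_dependent(normalized, cutoff=cfg.dependency_cutoff)
            _csv(calls_df, outdir / "dependency_calls.tsv", index_label="gene_id")
            outputs["dependency_calls"] = outdir / "dependency_calls.tsv"
            if cfg.expression:
                expr = pd.read_csv(cfg.expression, sep="\t", index_col=0)
                assoc_rows = []
                common_lines = [c for c in normalized.scores.columns if c in expr.columns]
                controls = set(raw.essential) | set(raw.nonessential)
                for gene in normalized.scores.index:
                    if gene in controls or gene not in expr.index:
                        continue
                    res = dep.expression_dependency_association(
                        expr.loc[gene, common_lines].to_numpy(),
                        normalized.scores.loc[gene, common_lines].to_numpy(),
                    )
                    assoc_rows.append(
                        {
                            "gene_id": gene,
                            "rho": res.rho,
                            "p_value": res.p_value,
                            "n": res.n,
                            "method": res.method,
                        }
                    )
                _csv(pd.DataFrame(assoc_rows), outdir / "dependency_association.tsv", index=False)
                outputs["dependency_association"] = outdir / "dependency_association.tsv"
            log.info(
                "[dependency] %d genes x %d lines, %d dependent calls",
                *calls_df.shape, int(calls_df.to_numpy().sum()),
            )
    except PipelineStageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError(stage, str(exc)) from exc

    # ---- stage 6: motif scan --------------------------------------------------
    stage = "motif_scan"
    try:
        if cfg.fasta and cfg.pwm:
            pwms = mot.read_jaspar(cfg.pwm)
            hit_rows = []
            for record in sorted(SeqIO.parse(cfg.fasta, "fasta"), key=lambda r: r.id):
                for pwm in pwms:
                    for h in mot.scan_sequence(
                        str(record.seq), pwm, p_max=cfg.p_max, sequence_id=record.id
                    ):
                        hit_rows.append(
                            {
                                "sequence_id": h.sequence_id,
                                "motif_id": h.motif_id,
                                "offset": h.offset,
                                "strand": h.strand,
                                "score_bits": h.score_bits,
                                "p_value": h.p_value,
                            }
                        )
            _csv(pd.DataFrame(hit_rows), outdir / "motif_hits.tsv", index=False)
            outputs["motif_hits"] = outdir / "motif_hits.tsv"
            log.info("[motif_scan] %d hits at p <= %g", len(hit_rows), cfg.p_max)
    except PipelineStageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError(stage, str(exc)) from exc

    # ---- report ----------------------------------------------------------------
    stage = "report"
    try:
        target_cats = [cohort_catalogs[c] for c in cfg.target_cohorts]
        rows = []
        for i, entry in enumerate(union.entries):
            shared_flag = all(
                any(entry.span.overlaps(e.span) for e in cat.entries)
                for cat in target_cats
            ) and len(target_cats) >= 2
            spec_score = (
                float(specificity.loc[entry.se_id]) if specificity is not None else float("nan")
            )
            rows.append(
                {
                    "se_id": entry.se_id,
                    "chrom": entry.span.chrom,
                    "start": entry.span.start,
                    "end": entry.span.end,
                    "support": entry.support,
                    "shared": shared_flag,
                    "looped_up_target": i in looped_up_se,
                    "recurrent_dup": entry.se_id in recurrent_se_ids,
                    "specificity": spec_score,
                }
            )
        report = pd.DataFrame(rows)
        sort_spec = report["specificity"].fillna(0.0)
        report = (
            report.assign(_spec=sort_spec)
            .sort_values(
                by=["shared", "looped_up_target", "recurrent_dup", "_spec", "chrom", "start"],
                ascending=[False, False, False, False, True, True],
                kind="mergesort",
            )
            .drop(columns="_spec")
            .reset_index(drop=True)
        )
        report.insert(0, "rank", range(1, len(report) + 1))
        report_path = outdir / "report.tsv"
        with open(report_path, "wt", encoding="utf-8") as fh:
            for key, value in sorted(_param_record(cfg).items()):
                fh.write(f"# {key}={value}\n")
            if not interaction_available:
                fh.write("# interaction: unavailable (no loop files supplied)\n")
            report.to_csv(fh, sep="\t", index=False, float_format="%.6g")
        outputs["report"] = report_path
        log.info("[report] %d SEs ranked -> %s", len(report), report_path)
    except PipelineStageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError(stage, str(exc)) from exc

    return PipelineResult(
        report=report,
        report_path=report_path,
        union_catalog=union,
        cohort_catalogs=cohort_catalogs,
        per_sample_ses=per_sample_ses,
        outputs=outputs,
    )


def _param_record(cfg: PipelineConfig) -> dict[str, object]:
    keys = (
        "stitch_distance",
        "tss_exclusion",
        "promoter_flank",
        "fdr_max",
        "fc_min",
        "min_support",
        "min_overlap_fraction",
        "min_cover",
        "min_donors",
        "dependency_cutoff",
        "p_max",
        "seed",
        "target_cohorts",
        "focal_sv_cohort",
    )
    return {k: getattr(cfg, k) for k in keys}


def _write_sample_outputs(outdir: Path, sample_id: str, calls) -> None:
    hk = calls.hockey
    write_bed(
        [
            BedInterval(r.span.chrom, r.span.start, r.span.end, name=f"SE_{i}", score=r.signal)
            for i, r in enumerate(calls.superenhancers)
        ],
        outdir / f"{sample_id}.se.bed",
    )
    rows = [
        {
            "rank": i + 1,
            "scaled_rank": hk.x[i],
            "scaled_signal": hk.y[i],
            "signal": r.signal,
            "label": "SE" if r.signal > hk.cutoff_signal else "typical",
            "chrom": r.span.chrom,
            "start": r.span.start,
            "end": r.span.end,
            "promoter_proximal": r.promoter_proximal,
        }
        for i, r in enumerate(hk.regions)
    ]
    _csv(pd.DataFrame(rows), outdir / f"{sample_id}.hockey.tsv", index=False)
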