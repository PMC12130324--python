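"""Synthetic multi-omic cohorts with planted ground truth.

The generator emits a complete, internally consistent dataset bundle on
disk — per-sample H3K27ac peak calls and signal tracks, per-cohort HiChIP
loop calls with FDRs, PCAWG-like structural-variant tables with a donor
manifest, differential-expression tables, a CRISPR gene-effect matrix with
essential/non-essential control lists, and enhancer sequences carrying a
planted motif — together with a TruthManifest recording every planted
object, so recall and precision of every pipeline stage can be scored
without any external download.

Planted super-enhancers are clusters of high-signal peaks (default 5 peaks,
~30x background density) present in every sample of their cohorts, modelled
on the separation between super-enhancers and typical enhancers in H3K27ac
hockey-stick profiles.  Two gastrointestinal cohorts (COREAD, STAD) share
two SEs and carry three private SEs each; a background-only outgroup cohort
emulates non-gastrointestinal cancer types so lineage specificity is
measurable.  One shared SE is recurrently duplicated in the GI SV cohort
only.  Each planted SE loops to one target gene whose expression is
upregulated; the duplicated SE's target gene is a planted dependency in
every cell line, with expression anti-correlated to its dependency score.

One pseudo-random stream per output family (peaks, signal, loops, SVs,
expression, dependency, sequence), all spawned from the master seed, so
changing one family's model does not perturb the others.  Identical
(config, seed) yields a byte-identical bundle.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import (
    GenomicInterval,
    SignalTrack,
    ValidationError,
    write_bed,
    write_bedpe_loops,
    write_gene_table,
    GeneModel,
    Loop,
)
from .sv import SvEvent, write_donor_manifest, write_sv_table
from .targets import DeRecord, write_de_table
from .dependency import GeneEffectMatrix, write_gene_effect
from .motifs import Pwm, write_jaspar

__all__ = [
    "GeneratorConfig",
    "PlantedSe",
    "TruthManifest",
    "SampleFiles",
    "DatasetBundle",
    "generate_cohorts",
    "score_recovery",
    "RecoveryScore",
]

RECOVERY_KINDS = (
    "SE",
    "shared-SE",
    "target-gene",
    "recurrent-amplicon",
    "dependent-pair",
    "motif-hit",
)


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic cohorts (all units in bp unless noted)."""

    # genome
    chrom_count: int = 2
    chrom_length: int = 10_000_000
    # genes
    gene_count: int = 300
    gene_body_length: int = 10_000
    # cohorts
    cohorts: tuple[str, str] = ("COREAD", "STAD")
    samples_per_cohort: int = 3
    outgroup_cohort: str = "OUTGROUP"
    outgroup_samples: int = 3
    # planted SEs
    shared_se_count: int = 2
    private_se_count: int = 3  # per cohort
    constituent_peaks: int = 5
    peak_width: int = 1_000
    intra_cluster_gap: int = 1_500
    target_gene_offset: int = 100_000
    # background peaks / signal model (log-normal densities)
    background_peaks_per_sample: int = 200
    background_peak_width: int = 800
    background_log_mu: float = 0.0
    background_log_sigma: float = 0.35
    se_signal_factor: float = 60.0
    se_log_sigma: float = 0.25
    peak_dropout: float = 0.05
    # loops
    decoy_loops_per_cohort: int = 50
    anchor_half_width: int = 1_000
    planted_fdr_max: float = 0.01
    decoy_fdr_min: float = 0.05
    # SVs
    sv_cohorts: tuple[str, str] = ("GI", "OTHER")
    donors_per_sv_cohort: int = 60
    recurrent_dup_donors: int = 8
    background_svs_per_donor: float = 2.0
    sv_length_min: int = 10_000
    sv_length_max: int = 200_000
    # expression
    planted_log2fc_mean: float = 2.0
    planted_log2fc_sd: float = 0.3
    null_log2fc_sd: float = 0.3
    # dependency
    n_control_genes: int = 30
    n_extra_effect_genes: int = 30
    planted_dependency: float = -0.9
    dependency_noise_sd: float = 0.05
    # motif
    motif_consensus: str = "CAGTTGGT"
    motif_consensus_count: int = 85
    motif_off_count: int = 5
    enhancer_count: int = 4
    enhancer_length: int = 1_500
    # master seed
    seed: int = 0

    def validate(self) -> None:
        cluster_len = (
            self.constituent_peaks * self.peak_width
            + (self.constituent_peaks - 1) * self.intra_cluster_gap
        )
        if cluster_len >= self.chrom_length:
            raise ValidationError("SE cluster longer than a chromosome")
        for name, rate in (("peak_dropout", self.peak_dropout),):
            if not (0.0 <= rate <= 1.0):
                raise ValidationError(f"{name} must lie in [0, 1]")
        for name, count in (
            ("chrom_count", self.chrom_count),
            ("gene_count", self.gene_count),
            ("samples_per_cohort", self.samples_per_cohort),
            ("constituent_peaks", self.constituent_peaks),
            ("donors_per_sv_cohort", self.donors_per_sv_cohort),
        ):
            if count < 1:
                raise ValidationError(f"{name} must be positive")
        n_planted = self.shared_se_count + 2 * self.private_se_count
        if self.gene_count < n_planted:
            raise ValidationError("need at least one gene per planted SE")
        if set(self.motif_consensus) - set("ACGT"):
            raise ValidationError("motif consensus must be over ACGT")

    @property
    def cluster_length(self) -> int:
        return (
            self.constituent_peaks * self.peak_width
            + (self.constituent_peaks - 1) * self.intra_cluster_gap
        )

    @property
    def n_planted_ses(self) -> int:
        return self.shared_se_count + 2 * self.private_se_count


@dataclass
class PlantedSe:
    se_id: str
    span: GenomicInterval
    cohorts: tuple[str, ...]
    target_gene: str
    peak_starts: tuple[int, ...]


@dataclass
class TruthManifest:
    """The generator's ground-truth ledger, sufficient to score every stage."""

    ses: list[PlantedSe]
    loops: dict[str, list[dict]]  # cohort -> planted loop records
    duplicated_se: str
    dup_cohort: str
    dup_donors: tuple[str, ...]
    upregulated: dict[str, dict[str, float]]  # cohort -> gene -> log2fc
    dependent_pairs: list[tuple[str, str]]  # (gene, cell line)
    motif: dict
    seed: int
    config: dict

    def ses_for_cohort(self, cohort: str | None) -> list[PlantedSe]:
        if cohort is None:
            return list(self.ses)
        return [s for s in self.ses if cohort in s.cohorts]

    def shared_spans(self) -> list[GenomicInterval]:
        return [s.span for s in self.ses if len(s.cohorts) > 1]

    def target_genes(self, cohort: str | None = None) -> set[str]:
        return {s.target_gene for s in self.ses_for_cohort(cohort)}

    def to_json(self, path: str | Path) -> None:
        payload = {
            "ses": [
                {
                    "se_id": s.se_id,
                    "chrom": s.span.chrom,
                    "start": s.span.start,
                    "end": s.span.end,
                    "cohorts": list(s.cohorts),
                    "target_gene": s.target_gene,
                    "peak_starts": list(s.peak_starts),
                }
                for s in self.ses
            ],
            "loops": self.loops,
            "duplicated_se": self.duplicated_se,
            "dup_cohort": self.dup_cohort,
            "dup_donors": list(self.dup_donors),
            "upregulated": self.upregulated,
            "dependent_pairs": [list(p) for p in self.dependent_pairs],
            "motif": self.motif,
            "seed": self.seed,
            "config": self.config,
        }
        with open(path, "wt", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthManifest":
        with open(path, "rt", encoding="utf-8") as fh:
            d = json.load(fh)
        ses = [
            PlantedSe(
                se_id=s["se_id"],
                span=GenomicInterval(s["chrom"], s["start"], s["end"]),
                cohorts=tuple(s["cohorts"]),
                target_gene=s["target_gene"],
                peak_starts=tuple(s["peak_starts"]),
            )
            for s in d["ses"]
        ]
        return cls(
            ses=ses,
            loops=d["loops"],
            duplicated_se=d["duplicated_se"],
            dup_cohort=d["dup_cohort"],
            dup_donors=tuple(d["dup_donors"]),
            upregulated=d["upregulated"],
            dependent_pairs=[tuple(p) for p in d["dependent_pairs"]],
            motif=d["motif"],
            seed=d["seed"],
            config=d["config"],
        )


@dataclass
class SampleFiles:
    sample_id: str
    peaks: Path
    signal: Path


@dataclass
class DatasetBundle:
    """File index of one generated dataset."""

    outdir: Path
    genes: Path
    samples: dict[str, list[SampleFiles]]  # cohort -> samples
    loops: dict[str, Path]  # cohort -> BEDPE
    sv: Path
    donors: Path
    de: dict[str, Path]  # cohort -> DE TSV
    gene_effect: Path
    essential: Path
    nonessential: Path
    expression: Path
    fasta: Path
    pwm: Path
    manifest: Path

    def to_json(self, path: str | Path) -> None:
        rel = lambda p: str(Path(p).relative_to(self.outdir))
        payload = {
            "genes": rel(self.genes),
            "samples": {
                c: [
                    {"sample_id": s.sample_id, "peaks": rel(s.peaks), "signal": rel(s.signal)}
                    for s in ss
                ]
                for c, ss in self.samples.items()
            },
            "loops": {c: rel(p) for c, p in self.loops.items()},
            "sv": rel(self.sv),
            "donors": rel(self.donors),
            "de": {c: rel(p) for c, p in self.de.items()},
            "gene_effect": rel(self.gene_effect),
            "essential": rel(self.essential),
            "nonessential": rel(self.nonessential),
            "expression": rel(self.expression),
            "fasta": rel(self.fasta),
            "pwm": rel(self.pwm),
            "manifest": rel(self.manifest),
        }
        with open(path, "wt", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_dir(cls, outdir: str | Path) -> "DatasetBundle":
        outdir = Path(outdir)
        with open(outdir / "bundle.json", "rt", encoding="utf-8") as fh:
            d = json.load(fh)
        ab = lambda p: outdir / p
        return cls(
            outdir=outdir,
            genes=ab(d["genes"]),
            samples={
                c: [
                    SampleFiles(s["sample_id"], ab(s["peaks"]), ab(s["signal"]))
                    for s in ss
                ]
                for c, ss in d["samples"].items()
            },
            loops={c: ab(p) for c, p in d["loops"].items()},
            sv=ab(d["sv"]),
            donors=ab(d["donors"]),
            de={c: ab(p) for c, p in d["de"].items()},
            gene_effect=ab(d["gene_effect"]),
            essential=ab(d["essential"]),
            nonessential=ab(d["nonessential"]),
            expression=ab(d["expression"]),
            fasta=ab(d["fasta"]),
            pwm=ab(d["pwm"]),
            manifest=ab(d["manifest"]),
        )


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _chrom_name(i: int) -> str:
    return f"chr{i + 1}"


def _plan_ses(cfg: GeneratorConfig) -> list[PlantedSe]:
    """Deterministic SE slots: alternate chromosomes, 2 Mb apart."""
    ses: list[PlantedSe] = []
    n = cfg.n_planted_ses
    for k in range(n):
        chrom = _chrom_name(k % cfg.chrom_count)
        start = 1_500_000 + (k // cfg.chrom_count) * 2_000_000
        end = start + cfg.cluster_length
        if end + cfg.target_gene_offset + cfg.gene_body_length >= cfg.chrom_length:
            raise ValidationError("planted SE layout exceeds chromosome bounds")
        if k < cfg.shared_se_count:
            cohorts = cfg.cohorts
        elif k < cfg.shared_se_count + cfg.private_se_count:
            cohorts = (cfg.cohorts[0],)
        else:
            cohorts = (cfg.cohorts[1],)
        peak_starts = tuple(
            start + i * (cfg.peak_width + cfg.intra_cluster_gap)
            for i in range(cfg.constituent_peaks)
        )
        ses.append(
            PlantedSe(
                se_id=f"SE{k:02d}",
                span=GenomicInterval(chrom, start, end),
                cohorts=cohorts,
                target_gene=f"GT{k:03d}",
                peak_starts=peak_starts,
            )
        )
    return ses


def _plan_genes(cfg: GeneratorConfig, ses: list[PlantedSe]) -> list[GeneModel]:
    genes: list[GeneModel] = []
    for s in ses:
        tss = s.span.start + cfg.target_gene_offset
        body = GenomicInterval(s.span.chrom, tss, tss + cfg.gene_body_length, "+")
        genes.append(GeneModel(s.target_gene, s.target_gene, body))
    # background genes on a grid, kept clear of planted clusters
    exclusion = 150_000
    needed = cfg.gene_count - len(genes)
    step = 50_000
    placed = 0
    idx = 0
    pos = 200_000
    chrom_i = 0
    while placed < needed:
        chrom = _chrom_name(chrom_i)
        if pos + cfg.gene_body_length > cfg.chrom_length - 200_000:
            chrom_i += 1
            pos = 200_000
            if chrom_i >= cfg.chrom_count:
                raise ValidationError("genome too small for requested gene count")
            continue
        clear = all(
            s.span.chrom != chrom
            or not (s.span.start - exclusion < pos < s.span.end + exclusion)
            for s in ses
        )
        if clear:
            strand = "+" if idx % 2 == 0 else "-"
            body = GenomicInterval(chrom, pos, pos + cfg.gene_body_length, strand)
            genes.append(GeneModel(f"G{idx:04d}", f"G{idx:04d}", body))
            placed += 1
            idx += 1
        pos += step
    genes.sort(key=lambda g: (g.body.chrom, g.body.start, g.gene_id))
    return genes


def _sample_ids(cfg: GeneratorConfig) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    for cohort in cfg.cohorts:
        out[cohort] = [f"{cohort}_S{i}" for i in range(cfg.samples_per_cohort)]
    if cfg.outgroup_samples > 0:
        out[cfg.outgroup_cohort] = [
            f"{cfg.outgroup_cohort}_S{i}" for i in range(cfg.outgroup_samples)
        ]
    return out


def generate_cohorts(
    config: GeneratorConfig, outdir: str | Path
) -> tuple[DatasetBundle, TruthManifest]:
    """Write a complete synthetic dataset bundle and its truth manifest."""
    cfg = config
    cfg.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "samples").mkdir(exist_ok=True)

    master = np.random.SeedSequence(cfg.seed)
    streams = {
        name: np.random.default_rng(child)
        for name, child in zip(
            ("peaks", "signal", "loops", "sv", "expression", "dependency", "sequence"),
            master.spawn(7),
        )
    }

    ses = _plan_ses(cfg)
    genes = _plan_genes(cfg, ses)
    genes_path = outdir / "genes.tsv"
    write_gene_table(genes, genes_path)
    gene_by_id = {g.gene_id: g for g in genes}

    samples = _sample_ids(cfg)
    sample_files: dict[str, list[SampleFiles]] = {}
    rng_pk = streams["peaks"]
    rng_sig = streams["signal"]
    for cohort in sorted(samples):
        sample_files[cohort] = []
        cohort_ses = [s for s in ses if cohort in s.cohorts]
        for sample_id in samples[cohort]:
            peaks, segs = _make_sample(cfg, cohort_ses, ses, rng_pk, rng_sig)
            ppath = outdir / "samples" / f"{sample_id}.peaks.bed"
            spath = outdir / "samples" / f"{sample_id}.signal.bedgraph"
            write_bed(peaks, ppath)
            SignalTrack(segs).to_bedgraph(spath)
            sample_files[cohort].append(SampleFiles(sample_id, ppath, spath))

    loops_paths: dict[str, Path] = {}
    truth_loops: dict[str, list[dict]] = {}
    rng_lp = streams["loops"]
    for cohort in cfg.cohorts:
        cohort_ses = [s for s in ses if cohort in s.cohorts]
        loops, records = _make_loops(cfg, cohort_ses, ses, gene_by_id, genes, rng_lp)
        path = outdir / f"{cohort}.loops.bedpe"
        write_bedpe_loops(loops, path)
        loops_paths[cohort] = path
        truth_loops[cohort] = records

    rng_sv = streams["sv"]
    dup_se = ses[0]
    events, donors, dup_donors = _make_svs(cfg, ses, dup_se, rng_sv)
    sv_path = outdir / "sv.tsv"
    donors_path = outdir / "donors.tsv"
    write_sv_table(events, sv_path)
    write_donor_manifest(donors, donors_path)

    rng_de = streams["expression"]
    de_paths: dict[str, Path] = {}
    upregulated: dict[str, dict[str, float]] = {}
    for cohort in cfg.cohorts:
        planted = sorted(s.target_gene for s in ses if cohort in s.cohorts)
        records, fcs = _make_de(cfg, genes, planted, rng_de)
        path = outdir / f"{cohort}.de.tsv"
        write_de_table(records, path)
        de_paths[cohort] = path
        upregulated[cohort] = fcs

    rng_dep = streams["dependency"]
    lines = [sid for cohort in cfg.cohorts for sid in samples[cohort]]
    matrix, dependent_pairs, norm_dep = _make_gene_effect(cfg, ses, dup_se, lines, rng_dep)
    ge_path = outdir / "gene_effect.tsv"
    ess_path = outdir / "essential_controls.txt"
    neg_path = outdir / "nonessential_controls.txt"
    write_gene_effect(matrix, ge_path)
    _write_list(matrix.essential, ess_path)
    _write_list(matrix.nonessential, neg_path)

    expr_path = outdir / "expression.tsv"
    _make_expression(cfg, matrix, dup_se.target_gene, norm_dep, rng_de, expr_path)

    rng_seq = streams["sequence"]
    fasta_path = outdir / "enhancers.fa"
    pwm_path = outdir / "motifs.jaspar"
    motif_truth = _make_sequences(cfg, rng_seq, fasta_path, pwm_path)

    manifest = TruthManifest(
        ses=ses,
        loops=truth_loops,
        duplicated_se=dup_se.se_id,
        dup_cohort=cfg.sv_cohorts[0],
        dup_donors=dup_donors,
        upregulated=upregulated,
        dependent_pairs=dependent_pairs,
        motif=motif_truth,
        seed=cfg.seed,
        config=dataclasses.asdict(cfg),
    )
    manifest_path = outdir / "truth.json"
    manifest.to_json(manifest_path)

    bundle = DatasetBundle(
        outdir=outdir,
        genes=genes_path,
        samples=sample_files,
        loops=loops_paths,
        sv=sv_path,
        donors=donors_path,
        de=de_paths,
        gene_effect=ge_path,
        essential=ess_path,
        nonessential=neg_path,
        expression=expr_path,
        fasta=fasta_path,
        pwm=pwm_path,
        manifest=manifest_path,
    )
    bundle.to_json(outdir / "bundle.json")
    return bundle, manifest


def _make_sample(
    cfg: GeneratorConfig,
    cohort_ses: list[PlantedSe],
    all_ses: list[PlantedSe],
    rng_pk: np.random.Generator,
    rng_sig: np.random.Generator,
) -> tuple[list[GenomicInterval], list[tuple[str, int, int, float]]]:
    """One sample's peak set and constant-per-peak signal segments."""
    margin = 50_000
    peaks: list[GenomicInterval] = []
    values: list[float] = []
    # background peaks, kept clear of every planted cluster and of each other
    occupied: dict[str, list[tuple[int, int]]] = {}
    placed = 0
    while placed < cfg.background_peaks_per_sample:
        chrom = _chrom_name(int(rng_pk.integers(cfg.chrom_count)))
        start = int(rng_pk.integers(margin, cfg.chrom_length - margin))
        end = start + cfg.background_peak_width
        if any(
            s.span.chrom == chrom
            and s.span.start - margin < start < s.span.end + margin
            for s in all_ses
        ):
            continue
        if any(start < e and end > b for b, e in occupied.get(chrom, ())):
            continue
        occupied.setdefault(chrom, []).append((start, end))
        peaks.append(GenomicInterval(chrom, start, start + cfg.background_peak_width))
        values.append(
            float(np.exp(rng_sig.normal(cfg.background_log_mu, cfg.background_log_sigma)))
        )
        placed += 1
    # planted constituent peaks (subject to dropout)
    for s in cohort_ses:
        for pstart in s.peak_starts:
            if rng_pk.random() < cfg.peak_dropout:
                continue
            peaks.append(GenomicInterval(s.span.chrom, pstart, pstart + cfg.peak_width))
            values.append(
                float(
                    cfg.se_signal_factor
                    * np.exp(rng_sig.normal(0.0, cfg.se_log_sigma))
                )
            )
    order = sorted(range(len(peaks)), key=lambda i: (peaks[i].chrom, peaks[i].start))
    peaks = [peaks[i] for i in order]
    values = [values[i] for i in order]
    segs = [(p.chrom, p.start, p.end, v) for p, v in zip(peaks, values)]
    return peaks, segs


def _make_loops(
    cfg: GeneratorConfig,
    cohort_ses: list[PlantedSe],
    all_ses: list[PlantedSe],
    gene_by_id: Mapping[str, GeneModel],
    genes: list[GeneModel],
    rng: np.random.Generator,
) -> tuple[list[Loop], list[dict]]:
    loops: list[Loop] = []
    records: list[dict] = []
    hw = cfg.anchor_half_width
    for s in cohort_ses:
        mid = s.span.midpoint
        gene = gene_by_id[s.target_gene]
        tss = gene.tss_pos
        a1 = GenomicInterval(s.span.chrom, mid - hw, mid + hw)
        a2 = GenomicInterval(gene.body.chrom, max(0, tss - hw), tss + hw)
        fdr = float(rng.uniform(0.0, cfg.planted_fdr_max))
        pet = int(5 + rng.poisson(25))
        loops.append(Loop(a1, a2, pet, fdr))
        records.append(
            {
                "se_id": s.se_id,
                "gene_id": s.target_gene,
                "anchor1": [a1.chrom, a1.start, a1.end],
                "anchor2": [a2.chrom, a2.start, a2.end],
                "fdr": fdr,
                "pet_count": pet,
            }
        )
    # decoy loops anchored away from planted SEs and from every promoter
    margin = 20_000
    tss_by_chrom: dict[str, list[int]] = {}
    for g in genes:
        tss_by_chrom.setdefault(g.body.chrom, []).append(g.tss_pos)

    def clear(chrom: str, pos: int) -> bool:
        if any(
            s.span.chrom == chrom and s.span.start - margin < pos < s.span.end + margin
            for s in all_ses
        ):
            return False
        return all(abs(pos - t) > margin for t in tss_by_chrom.get(chrom, ()))

    made = 0
    while made < cfg.decoy_loops_per_cohort:
        chrom = _chrom_name(int(rng.integers(cfg.chrom_count)))
        p1 = int(rng.integers(margin, cfg.chrom_length - margin))
        p2 = int(rng.integers(margin, cfg.chrom_length - margin))
        if abs(p1 - p2) < 4 * hw or not (clear(chrom, p1) and clear(chrom, p2)):
            continue
        fdr = float(rng.uniform(cfg.decoy_fdr_min, 1.0))
        pet = int(1 + rng.poisson(4))
        loops.append(
            Loop(
                GenomicInterval(chrom, p1 - hw, p1 + hw),
                GenomicInterval(chrom, p2 - hw, p2 + hw),
                pet,
                fdr,
            )
        )
        made += 1
    loops.sort(
        key=lambda lp: (lp.anchor1.chrom, lp.anchor1.start, lp.anchor2.start, lp.fdr)
    )
    return loops, records


def _make_svs(
    cfg: GeneratorConfig,
    ses: list[PlantedSe],
    dup_se: PlantedSe,
    rng: np.random.Generator,
) -> tuple[list[SvEvent], dict[str, str], tuple[str, ...]]:
    donors: dict[str, str] = {}
    for cohort in cfg.sv_cohorts:
        for i in range(cfg.donors_per_sv_cohort):
            donors[f"{cohort}_D{i:03d}"] = cohort
    events: list[SvEvent] = []
    dup_cohort = cfg.sv_cohorts[0]
    dup_donors = tuple(
        f"{dup_cohort}_D{i:03d}" for i in range(cfg.recurrent_dup_donors)
    )
    for donor in dup_donors:
        pad_l = int(rng.integers(5_000, 20_000))
        pad_r = int(rng.integers(5_000, 20_000))
        span = GenomicInterval(
            dup_se.span.chrom,
            max(0, dup_se.span.start - pad_l),
            dup_se.span.end + pad_r,
        )
        events.append(SvEvent(donor, dup_cohort, "DUP", span))
    # background SVs; background DUPs are kept off every planted SE
    margin = 20_000
    for donor in sorted(donors):
        cohort = donors[donor]
        for _ in range(int(rng.poisson(cfg.background_svs_per_donor))):
            sv_type = str(rng.choice(["DUP", "DEL", "INV"], p=[0.4, 0.4, 0.2]))
            for _attempt in range(100):
                chrom = _chrom_name(int(rng.integers(cfg.chrom_count)))
                length = int(rng.integers(cfg.sv_length_min, cfg.sv_length_max))
                start = int(rng.integers(0, cfg.chrom_length - length))
                span = GenomicInterval(chrom, start, start + length)
                if sv_type != "DUP" or all(
                    s.span.chrom != chrom
                    or span.end <= s.span.start - margin
                    or span.start >= s.span.end + margin
                    for s in ses
                ):
                    break
            events.append(SvEvent(donor, cohort, sv_type, span))
    return events, donors, dup_donors


def _make_de(
    cfg: GeneratorConfig,
    genes: list[GeneModel],
    planted_up: list[str],
    rng: np.random.Generator,
) -> tuple[list[DeRecord], dict[str, float]]:
    records: list[DeRecord] = []
    fcs: dict[str, float] = {}
    planted = set(planted_up)
    for g in genes:
        if g.gene_id in planted:
            fc = float(rng.normal(cfg.planted_log2fc_mean, cfg.planted_log2fc_sd))
            fc = max(fc, 0.5)  # planted targets are genuinely upregulated
            fdr = float(10.0 ** -rng.uniform(4.0, 8.0))
            fcs[g.gene_id] = fc
        else:
            fc = float(rng.normal(0.0, cfg.null_log2fc_sd))
            fdr = float(rng.uniform(0.0, 1.0))
        records.append(DeRecord(g.gene_id, fc, fdr))
    return records, fcs


def _make_gene_effect(
    cfg: GeneratorConfig,
    ses: list[PlantedSe],
    dup_se: PlantedSe,
    lines: list[str],
    rng: np.random.Generator,
) -> tuple[GeneEffectMatrix, list[tuple[str, str]], dict[str, float]]:
    essential = tuple(f"ESS{i:03d}" for i in range(cfg.n_control_genes))
    nonessential = tuple(f"NEG{i:03d}" for i in range(cfg.n_control_genes))
    targets = [s.target_gene for s in ses]
    extra = [f"G{idx:04d}" for idx in range(cfg.n_extra_effect_genes)]
    gene_rows = list(essential) + list(nonessential) + targets + extra
    n_lines = len(lines)

    norm = pd.DataFrame(0.0, index=gene_rows, columns=lines)
    norm.loc[list(essential)] = rng.normal(-1.0, cfg.dependency_noise_sd, (len(essential), n_lines))
    norm.loc[list(nonessential)] = rng.normal(0.0, cfg.dependency_noise_sd, (len(nonessential), n_lines))
    others = targets + extra
    norm.loc[others] = np.clip(
        rng.normal(0.0, 2 * cfg.dependency_noise_sd, (len(others), n_lines)), -0.4, None
    )
    dependent_pairs = [(dup_se.target_gene, line) for line in lines]
    # graded dependency across lines (all past the -0.5 call threshold), so
    # the expression-dependency association has real signal to detect
    planted_scores = np.clip(
        np.linspace(
            cfg.planted_dependency - 0.35, cfg.planted_dependency + 0.28, n_lines
        )
        + rng.normal(0.0, 0.02, n_lines),
        None,
        -0.58,
    )
    norm.loc[dup_se.target_gene] = planted_scores

    # per-line affine distortion: the raw matrix arrives un-normalized
    scale = rng.uniform(0.8, 1.5, n_lines)
    shift = rng.uniform(-0.5, 0.5, n_lines)
    raw = norm * scale + shift
    matrix = GeneEffectMatrix(scores=raw, essential=essential, nonessential=nonessential)
    norm_dep = {line: float(planted_scores[i]) for i, line in enumerate(lines)}
    return matrix, dependent_pairs, norm_dep


def _make_expression(
    cfg: GeneratorConfig,
    matrix: GeneEffectMatrix,
    dep_gene: str,
    norm_dep: dict[str, float],
    rng: np.random.Generator,
    path: Path,
) -> None:
    lines = list(matrix.scores.columns)
    expr = pd.DataFrame(
        np.exp(rng.normal(2.0, 0.5, matrix.scores.shape)),
        index=matrix.scores.index,
        columns=lines,
    )
    # the planted dependency gene: expression rises with dependency strength
    expr.loc[dep_gene] = [
        6.0 + 4.0 * (-norm_dep[line]) + float(rng.normal(0.0, 0.01)) for line in lines
    ]
    expr.to_csv(path, sep="\t", float_format="%.6g")


def _make_sequences(
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    fasta_path: Path,
    pwm_path: Path,
) -> dict:
    bases = np.array(list("ACGT"))
    records = []
    seqs: dict[str, str] = {}
    for i in range(cfg.enhancer_count):
        name = f"e{i + 1}"
        seqs[name] = "".join(rng.choice(bases, cfg.enhancer_length))
    motif_len = len(cfg.motif_consensus)
    target = f"e{cfg.enhancer_count}"
    offset = int(rng.integers(100, cfg.enhancer_length - motif_len - 100))
    s = seqs[target]
    seqs[target] = s[:offset] + cfg.motif_consensus + s[offset + motif_len :]
    for name in sorted(seqs):
        records.append(SeqRecord(Seq(seqs[name]), id=name, description=""))
    SeqIO.write(records, str(fasta_path), "fasta")

    counts = np.full((4, motif_len), float(cfg.motif_off_count))
    for j, base in enumerate(cfg.motif_consensus):
        counts["ACGT".index(base), j] = float(cfg.motif_consensus_count)
    pwm = Pwm(motif_id="SYNMYB1", counts=counts)
    write_jaspar([pwm], pwm_path)
    return {
        "motif_id": "SYNMYB1",
        "sequence_id": target,
        "offset": offset,
        "strand": "+",
        "consensus": cfg.motif_consensus,
    }


def _write_list(items: Iterable[str], path: Path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for item in items:
            fh.write(f"{item}\n")


# ---------------------------------------------------------------------------
# recovery scoring
# ---------------------------------------------------------------------------

@dataclass
class RecoveryScore:
    recall: float
    precision: float  # NaN (flagged) when there are no calls
    matched: list[tuple]
    n_truth: int
    n_calls: int

    @property
    def precision_defined(self) -> bool:
        return self.n_calls > 0


def _reciprocal_match(a: GenomicInterval, b: GenomicInterval, frac: float = 0.5) -> bool:
    bp = a.overlap_bp(b)
    return bp >= frac * a.length and bp >= frac * b.length


def score_recovery(
    calls,
    truth: TruthManifest,
    kind: str,
    cohort: str | None = None,
) -> RecoveryScore:
    """Recall/precision of a module's calls against the planted truth.

    kinds: SE and shared-SE match intervals by >= 50% reciprocal overlap
    (``cohort`` restricts SE truth to one cohort's planted set);
    recurrent-amplicon matches (interval, cohort) rows the same way;
    target-gene and dependent-pair match by identity; motif-hit matches
    (sequence_id, offset, strand) with the offset within +/- 1.
    """
    if kind not in RECOVERY_KINDS:
        raise ValidationError(f"unknown recovery kind {kind!r}; one of {RECOVERY_KINDS}")

    if kind in ("SE", "shared-SE"):
        truth_spans = (
            truth.shared_spans() if kind == "shared-SE" else [s.span for s in truth.ses_for_cohort(cohort)]
        )
        calls = list(calls)
        matched = [
            (str(t), str(c))
            for t in truth_spans
            for c in calls
            if _reciprocal_match(t, c)
        ]
        hit_truth = {m[0] for m in matched}
        hit_calls = {m[1] for m in matched}
        return _score(
            len(hit_truth), len(truth_spans), len(hit_calls), len(calls), matched
        )

    if kind == "recurrent-amplicon":
        truth_rows = [(s.span, truth.dup_cohort) for s in truth.ses if s.se_id == truth.duplicated_se]
        calls = list(calls)
        matched = [
            (str(t), str(c))
            for t, tc in truth_rows
            for c, cc in calls
            if cc == tc and _reciprocal_match(t, c)
        ]
        hit_truth = {m[0] for m in matched}
        hit_calls = {m[1] for m in matched}
        return _score(len(hit_truth), len(truth_rows), len(hit_calls), len(calls), matched)

    if kind == "target-gene":
        truth_set = truth.target_genes(cohort)
        call_set = set(calls)
        matched = sorted(truth_set & call_set)
        return _score(len(matched), len(truth_set), len(matched), len(call_set), [(g, g) for g in matched])

    if kind == "dependent-pair":
        truth_set = {tuple(p) for p in truth.dependent_pairs}
        call_set = {tuple(p) for p in calls}
        matched = sorted(truth_set & call_set)
        return _score(len(matched), len(truth_set), len(matched), len(call_set), [(p, p) for p in matched])

    # motif-hit
    t = truth.motif
    calls = list(calls)
    matched = [
        ((t["sequence_id"], t["offset"], t["strand"]), c)
        for c in calls
        if c[0] == t["sequence_id"]
        and abs(int(c[1]) - int(t["offset"])) <= 1
        and c[2] == t["strand"]
    ]
    hit_truth = 1 if matched else 0
    hit_calls = len({m[1] for m in matched})
    return _score(hit_truth, 1, hit_calls, len(calls), matched)


def _score(
    n_matched_truth: int,
    n_truth: int,
    n_matched_calls: int,
    n_calls: int,
    matched: list,
) -> RecoveryScore:
    recall = n_matched_truth / n_truth if n_truth else float("nan")
    precision = n_matched_calls / n_calls if n_calls else float("nan")
    return RecoveryScore(
        recall=recall,
        precision=precision,
        matched=matched,
        n_truth=n_truth,
        n_calls=n_calls,
    )
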