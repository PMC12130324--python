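"""Promoter windows, loop assignment, nearest gene and expression integration."""

import numpy as np
import pytest

from sescout.core import GeneModel, GenomicInterval, Loop
from sescout.targets import (
    DeRecord,
    categorize_genes,
    direct_targets,
    loop_assign,
    nearest_gene,
    promoter_windows,
)


def iv(start, end, chrom="chr1", strand="."):
    return GenomicInterval(chrom, start, end, strand)


def gene(gid, start, end, strand="+", chrom="chr1"):
    return GeneModel(gid, gid, GenomicInterval(chrom, start, end, strand))


class TestPromoterWindows:
    def test_plus_strand(self):
        w = promoter_windows([gene("g", 10_000, 20_000, "+")], flank=2500)["g"]
        assert (w.start, w.end) == (7_500, 12_500)

    def test_minus_strand_centered_at_body_end(self):
        w = promoter_windows([gene("g", 10_000, 20_000, "-")], flank=2500)["g"]
        assert (w.start, w.end) == (17_499, 22_499)

    def test_clipped_at_zero(self):
        w = promoter_windows([gene("g", 1_000, 5_000, "+")], flank=2500)["g"]
        assert (w.start, w.end) == (0, 3_500)


class TestLoopAssign:
    def _setup(self):
        ses = [iv(100_000, 130_000)]
        genes = [gene("gA", 10_000, 20_000, "+")]
        promoters = promoter_windows(genes)  # gA window [7500, 12500)
        return ses, promoters

    def test_significant_loop_emits_pair(self):
        ses, promoters = self._setup()
        loop = Loop(iv(9_000, 11_000), iv(105_000, 107_000), 10, 0.01)
        pairs = loop_assign(ses, [loop], promoters)
        assert len(pairs) == 1
        p = pairs[0]
        assert (p.se_index, p.gene_id, p.best_fdr, p.pet_count) == (0, "gA", 0.01, 10)

    def test_fdr_threshold_is_strict(self):
        ses, promoters = self._setup()
        loop = Loop(iv(9_000, 11_000), iv(105_000, 107_000), 10, 0.05)
        assert loop_assign(ses, [loop], promoters) == []

    def test_best_fdr_is_minimum_over_loops(self):
        ses, promoters = self._setup()
        loops = [
            Loop(iv(9_000, 11_000), iv(105_000, 107_000), 4, 0.03),
            Loop(iv(8_000, 10_000), iv(110_000, 112_000), 9, 0.002),
        ]
        (p,) = loop_assign(ses, loops, promoters)
        assert p.best_fdr == 0.002 and p.pet_count == 9

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_anchor_overlap_oracle(self, seed):
        rng = np.random.default_rng(seed)
        ses = [
            iv(int(s), int(s) + int(rng.integers(5_000, 30_000)))
            for s in rng.integers(0, 2_000_000, 20)
        ]
        genes = [
            gene(f"g{k:03d}", int(s), int(s) + 10_000, strand=str(rng.choice(["+", "-"])))
            for k, s in enumerate(rng.integers(0, 2_000_000, 50))
        ]
        promoters = promoter_windows(genes)
        loops = []
        for _ in range(100):
            a = int(rng.integers(0, 2_000_000))
            b = int(rng.integers(0, 2_000_000))
            loops.append(
                Loop(
                    iv(a, a + 2000),
                    iv(b, b + 2000),
                    int(rng.integers(1, 50)),
                    float(rng.uniform(0, 1)),
                )
            )
        got = {(p.se_index, p.gene_id) for p in loop_assign(ses, loops, promoters)}
        expected = set()
        for lp in loops:
            if lp.fdr >= 0.05:
                continue
            for si, se in enumerate(ses):
                for gid, w in promoters.items():
                    if (se.overlap_bp(lp.anchor1) and w.overlap_bp(lp.anchor2)) or (
                        se.overlap_bp(lp.anchor2) and w.overlap_bp(lp.anchor1)
                    ):
                        expected.add((si, gid))
        assert got == expected

    def test_monotone_in_fdr_max(self):
        rng = np.random.default_rng(17)
        ses = [iv(int(s), int(s) + 10_000) for s in rng.integers(0, 500_000, 10)]
        genes = [gene(f"g{k}", int(s), int(s) + 5_000) for k, s in enumerate(rng.integers(0, 500_000, 20))]
        promoters = promoter_windows(genes)
        loops = [
            Loop(
                iv(int(a), int(a) + 2000),
                iv(int(b), int(b) + 2000),
                1,
                float(rng.uniform(0, 0.3)),
            )
            for a, b in zip(rng.integers(0, 500_000, 80), rng.integers(0, 500_000, 80))
        ]
        strict = {(p.se_index, p.gene_id) for p in loop_assign(ses, loops, promoters, fdr_max=0.01)}
        relaxed = {(p.se_index, p.gene_id) for p in loop_assign(ses, loops, promoters, fdr_max=0.2)}
        assert strict <= relaxed


class TestNearestGene:
    def test_min_distance_wins(self):
        genes = [gene("far", 9_000, 19_000), gene("near", 4_000, 14_000)]
        (a,) = nearest_gene([iv(4_500, 5_500)], genes)  # midpoint 5000
        assert a.gene_id == "near" and a.distance == 1_000 and not a.tie

    def test_equidistant_tie_flagged_lexicographic(self):
        # site midpoint 5000; TSSs at 6000 (+) and 4000 (-) -> both 1000 away
        genes = [gene("gB", 6_000, 16_000), gene("gA", 2_000, 4_001, "-")]
        (a,) = nearest_gene([iv(4_500, 5_500)], genes)
        assert a.gene_id == "gA" and a.tie

    def test_unassigned_without_genes_on_chrom(self):
        (a,) = nearest_gene([iv(0, 100, chrom="chrX")], [gene("g", 0, 100)])
        assert a.gene_id is None

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        sites = [iv(int(s), int(s) + 200) for s in rng.integers(0, 1_000_000, 300)]
        genes = [
            gene(f"g{k:03d}", int(s), int(s) + 8_000, strand=str(rng.choice(["+", "-"])))
            for k, s in enumerate(rng.integers(0, 1_000_000, 40))
        ]
        got = nearest_gene(sites, genes)
        for site, a in zip(sites, got):
            mid = site.midpoint
            best = min(genes, key=lambda g: (abs(g.tss_pos - mid), g.gene_id))
            assert a.gene_id == best.gene_id


class TestCategorizeGenes:
    def _pairs(self, *gids):
        from sescout.targets import SeGenePair

        return [SeGenePair(0, g, 0.01, 5) for g in gids]

    def test_both_flags(self):
        cats, counts = categorize_genes(
            ["g1"], self._pairs("g1"), [DeRecord("g1", 1.2, 0.01)]
        )
        assert cats[0].category == "interaction+up"
        assert counts["interaction+up"] == 1

    def test_interaction_only(self):
        cats, _ = categorize_genes(
            ["g1"], self._pairs("g1"), [DeRecord("g1", -0.5, 0.01)]
        )
        assert cats[0].category == "interaction only"

    def test_unmeasured_never_silently_downgraded(self):
        cats, counts = categorize_genes(["g1"], self._pairs("g1"), [])
        assert cats[0].category == "unmeasured" and cats[0].is_upregulated is None
        assert sum(counts.values()) == 0

    def test_counts_partition_measured_genes(self):
        rng = np.random.default_rng(2)
        gids = [f"g{k}" for k in range(50)]
        de = [
            DeRecord(g, float(rng.normal(0, 1)), float(rng.uniform(0, 1)))
            for g in gids
        ]
        pairs = self._pairs(*rng.choice(gids, 20, replace=False))
        cats, counts = categorize_genes(gids, pairs, de)
        assert sum(counts.values()) == len([c for c in cats if c.measured]) == 50

    def test_raising_fc_min_never_adds_upregulated(self):
        de = [DeRecord("g1", 0.5, 0.01)]
        _, lo = categorize_genes(["g1"], [], de, fc_min=0.0)
        _, hi = categorize_genes(["g1"], [], de, fc_min=1.0)
        assert hi["up only"] <= lo["up only"]


class TestDirectTargets:
    def test_set_intersection(self):
        de = [
            DeRecord("B", 1.0, 0.001),
            DeRecord("C", -2.0, 0.001),
            DeRecord("D", -1.0, 0.001),
        ]
        down, up = direct_targets({"A", "B", "C"}, de)
        assert up == {"B"} and down == {"C"}

    def test_empty_chip_set(self):
        assert direct_targets(set(), [DeRecord("A", 1.0, 0.001)]) == (set(), set())

    def test_disjoint_and_matches_set_oracle(self):
        rng = np.random.default_rng(12)
        gids = [f"g{k:04d}" for k in range(1000)]
        chip = set(rng.choice(gids, 400, replace=False))
        de = [
            DeRecord(g, float(rng.normal(0, 1)), float(rng.uniform(0, 0.2)))
            for g in rng.choice(gids, 600, replace=False)
        ]
        down, up = direct_targets(chip, de)
        assert not down & up
        exp_down = {r.gene_id for r in de if r.gene_id in chip and r.log2fc < 0 and r.fdr < 0.05}
        exp_up = {r.gene_id for r in de if r.gene_id in chip and r.log2fc > 0 and r.fdr < 0.05}
        assert (down, up) == (exp_down, exp_up)
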