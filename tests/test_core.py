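"""Coordinate model, interval algebra and file IO."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sescout.core import (
    BedInterval,
    GenomicInterval,
    Loop,
    ParseError,
    SignalTrack,
    ValidationError,
    aggregate_signal,
    overlap_pairs,
    read_bed,
    read_bedpe_loops,
    write_bed,
)


class TestGenomicInterval:
    def test_field_invariants(self):
        iv = GenomicInterval("chr1", 0, 100)
        assert (iv.chrom, iv.start, iv.end, len(iv)) == ("chr1", 0, 100, 100)

    @pytest.mark.parametrize(
        "chrom,start,end",
        [("chr1", 100, 100), ("chr1", 5, 3), ("chr1", -1, 10), ("", 0, 10)],
    )
    def test_invalid_intervals_rejected(self, chrom, start, end):
        with pytest.raises(ValidationError):
            GenomicInterval(chrom, start, end)

    def test_half_open_abutment_does_not_overlap(self):
        assert GenomicInterval("chr1", 0, 100).overlap_bp(
            GenomicInterval("chr1", 100, 200)
        ) == 0


class TestBedIO:
    def test_direct_field_mapping(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t0\t100\n")
        (iv,) = read_bed(p)
        assert (iv.chrom, iv.start, iv.end) == ("chr1", 0, 100)

    def test_zero_width_forbidden(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t100\t100\n")
        with pytest.raises(ValidationError, match="1"):
            read_bed(p)

    def test_track_header_skipped(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text(
            "track name=peaks\nchr1\t0\t10\nchr1\t20\t30\nchr2\t5\t8\n"
        )
        ivs = read_bed(p)
        assert len(ivs) == 3
        assert [iv.start for iv in ivs] == [0, 20, 5]  # input order preserved

    def test_malformed_line_names_line_number(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t0\t10\nchr1\tnope\t20\n")
        with pytest.raises(ParseError, match=":2"):
            read_bed(p)

    def test_round_trip_byte_identical(self, tmp_path):
        canonical = "chr1\t0\t100\tpeak1\t3.5\nchr1\t200\t300\tpeak2\t7\nchr2\t5\t80\tpeak3\t1\n"
        src = tmp_path / "in.bed"
        src.write_text(canonical)
        out = tmp_path / "out.bed"
        write_bed(read_bed(src), out)
        assert out.read_text() == canonical

    def test_alias_map_applied_at_read(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("1\t0\t10\n")
        (iv,) = read_bed(p, alias={"1": "chr1"})
        assert iv.chrom == "chr1"


class TestOverlapPairs:
    def test_simple_overlap(self):
        pairs = overlap_pairs(
            [GenomicInterval("chr1", 0, 100)], [GenomicInterval("chr1", 50, 150)]
        )
        assert pairs == [(0, 0, 50)]

    def test_half_open_abutment_empty(self):
        assert overlap_pairs(
            [GenomicInterval("chr1", 0, 100)], [GenomicInterval("chr1", 100, 200)]
        ) == []

    def test_min_bp_validation(self):
        with pytest.raises(ValidationError):
            overlap_pairs([], [], min_bp=0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    @pytest.mark.parametrize("n", [50, 200, 500])
    def test_matches_exhaustive_oracle(self, seed, n):
        from conftest import random_intervals

        rng = np.random.default_rng(seed)
        a = random_intervals(rng, n)
        b = random_intervals(rng, n)
        min_bp = int(rng.integers(1, 100))
        expected = sorted(
            (i, j, a[i].overlap_bp(b[j]))
            for i in range(len(a))
            for j in range(len(b))
            if a[i].overlap_bp(b[j]) >= min_bp
        )
        assert overlap_pairs(a, b, min_bp=min_bp) == expected

    def test_symmetric_under_swap(self):
        rng = np.random.default_rng(3)
        from conftest import random_intervals

        a = random_intervals(rng, 80)
        b = random_intervals(rng, 80)
        fwd = {(i, j, bp) for i, j, bp in overlap_pairs(a, b)}
        rev = {(j, i, bp) for i, j, bp in overlap_pairs(b, a)}
        assert fwd == rev


class TestSignalTrack:
    def test_constant_segment_mass(self):
        track = SignalTrack([("chr1", 0, 50, 2.0)])
        assert aggregate_signal(GenomicInterval("chr1", 0, 100), track) == 100.0

    def test_empty_track_is_zero(self):
        assert aggregate_signal(GenomicInterval("chr1", 0, 100), SignalTrack.empty()) == 0.0

    def test_matches_per_base_oracle(self):
        rng = np.random.default_rng(11)
        pos = np.sort(rng.choice(np.arange(1, 5000), size=100, replace=False))
        segs = []
        for s, e in zip(pos[::2], pos[1::2]):
            segs.append(("chr1", int(s), int(e), float(rng.uniform(0, 5))))
        track = SignalTrack(segs)
        region = GenomicInterval("chr1", 500, 4500)
        per_base = np.zeros(5000)
        for _, s, e, v in segs:
            per_base[s:e] += v
        assert aggregate_signal(region, track) == pytest.approx(
            per_base[500:4500].sum()
        )

    @given(st.integers(min_value=1, max_value=99))
    @settings(derandomize=True, max_examples=30)
    def test_invariant_to_segment_splitting(self, cut):
        whole = SignalTrack([("chr1", 0, 100, 3.0)])
        split = SignalTrack([("chr1", 0, cut, 3.0), ("chr1", cut, 100, 3.0)])
        region = GenomicInterval("chr1", 10, 90)
        assert aggregate_signal(region, whole) == pytest.approx(
            aggregate_signal(region, split)
        )

    def test_overlapping_segments_rejected(self):
        with pytest.raises(ValidationError):
            SignalTrack([("chr1", 0, 50, 1.0), ("chr1", 40, 80, 1.0)])

    def test_negative_values_rejected(self):
        with pytest.raises(ValidationError):
            SignalTrack([("chr1", 0, 50, -1.0)])


class TestBedpeLoops:
    def test_field_mapping(self, tmp_path):
        p = tmp_path / "l.bedpe"
        p.write_text("chr1\t9000\t11000\tchr1\t105000\t107000\t12\t0.01\n")
        (lp,) = read_bedpe_loops(p)
        assert lp.anchor1 == GenomicInterval("chr1", 9000, 11000)
        assert lp.anchor2 == GenomicInterval("chr1", 105000, 107000)
        assert (lp.pet_count, lp.fdr) == (12, 0.01)

    def test_fdr_out_of_range_rejected(self, tmp_path):
        p = tmp_path / "l.bedpe"
        p.write_text("chr1\t0\t10\tchr1\t50\t60\t3\t1.5\n")
        with pytest.raises(ValidationError):
            read_bedpe_loops(p)

    def test_anchor_canonicalization(self, tmp_path):
        lines = [
            "chr1\t105000\t107000\tchr1\t9000\t11000\t5\t0.02",
            "chr1\t0\t100\tchr1\t500\t600\t4\t0.5",
            "chr2\t900\t1000\tchr2\t100\t200\t2\t0.9",
            "chr1\t300\t400\tchr1\t700\t800\t8\t0.001",
            "chr2\t10\t20\tchr2\t30\t40\t1\t0.3",
        ]
        p = tmp_path / "l.bedpe"
        p.write_text("\n".join(lines) + "\n")
        loops = read_bedpe_loops(p)
        assert len(loops) == 5
        for lp in loops:
            assert (lp.anchor1.chrom, lp.anchor1.start) <= (
                lp.anchor2.chrom,
                lp.anchor2.start,
            )
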