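"""Interval algebra: BED I/O, merge/intersect/subtract/consensus semantics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from perichrom.intervals import (
    BedParseError,
    Genome,
    GenomicInterval,
    IntervalSet,
    consensus_union,
    coverage_fraction,
    intersect,
    merge,
    overlap_counts,
    read_bed,
    read_chrom_sizes,
    subtract_control,
    write_bed,
)

from conftest import (
    as_tuples,
    oracle_consensus_union,
    perbase,
    perbase_to_intervals,
    random_interval_set,
)


def iset(genome, triples):
    return IntervalSet(genome, [GenomicInterval(*t) for t in triples])


class TestGenome:
    def test_size_and_order(self, toy_genome):
        assert toy_genome.size == 1800
        assert toy_genome.names == ("chr1", "chr2")
        assert toy_genome.order("chr2") == 1

    @pytest.mark.parametrize(
        "chroms",
        [
            [("chr1", 100), ("chr1", 200)],  # duplicate name
            [("", 100)],  # empty name
            [("chr1", 0)],  # non-positive length
        ],
    )
    def test_invalid_genomes_rejected(self, chroms):
        with pytest.raises(ValueError):
            Genome(chroms)

    def test_interval_validation(self, toy_genome):
        with pytest.raises(ValueError):
            iset(toy_genome, [("chr1", 900, 1100)])  # beyond chromosome
        with pytest.raises(ValueError):
            iset(toy_genome, [("chr3", 0, 10)])  # unknown chromosome
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 50, 50)  # empty interval


class TestBedIO:
    def test_bed3_parse(self, tmp_path, toy_genome):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t0\t100\n")
        ivs = read_bed(p, toy_genome)
        assert as_tuples(ivs) == [("chr1", 0, 100)]

    def test_narrowpeak_keeps_name_and_signal(self, tmp_path, toy_genome):
        p = tmp_path / "a.narrowPeak"
        p.write_text("chr1\t10\t60\tpeak_1\t850\t.\t12.5\t30.1\t25.2\t22\n")
        ivs = read_bed(p, toy_genome, format="narrowPeak")
        (iv,) = list(ivs)
        assert (iv.name, iv.score) == ("peak_1", 12.5)

    def test_unknown_chrom_dropped_with_warning(self, tmp_path, toy_genome, caplog):
        p = tmp_path / "a.bed"
        p.write_text("chrUn_gl000220\t0\t50\nchr1\t5\t10\n")
        with caplog.at_level("WARNING"):
            ivs = read_bed(p, toy_genome)
        assert as_tuples(ivs) == [("chr1", 5, 10)]
        assert "dropped 1" in caplog.text

    def test_unknown_chrom_strict_raises(self, tmp_path, toy_genome):
        p = tmp_path / "a.bed"
        p.write_text("chrUn_gl000220\t0\t50\n")
        with pytest.raises(BedParseError, match="unknown chromosome"):
            read_bed(p, toy_genome, on_unknown_chrom="strict")

    @pytest.mark.parametrize(
        "line, match",
        [
            ("chr1\t100\t50", "invalid interval"),
            ("chr1\t0", "columns"),
            ("chr1\tzero\t10", "non-integer"),
        ],
    )
    def test_malformed_lines_report_line_number(self, tmp_path, toy_genome, line, match):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t0\t10\n" + line + "\n")
        with pytest.raises(BedParseError, match=match) as err:
            read_bed(p, toy_genome)
        assert ":2" in str(err.value)

    def test_bed6_roundtrip(self, tmp_path, toy_genome):
        ivs = IntervalSet(
            toy_genome,
            [GenomicInterval("chr1", 0, 100, "a", 5.0), GenomicInterval("chr2", 10, 20)],
        )
        p = tmp_path / "out.bed"
        write_bed(ivs, p, header=["test"])
        back = read_bed(p, toy_genome, format="bed6")
        assert as_tuples(back) == as_tuples(ivs)
        assert list(back)[0].name == "a"

    def test_chrom_sizes_roundtrip(self, tmp_path):
        p = tmp_path / "g.chrom.sizes"
        p.write_text("chr1\t1000\nchr2\t800\n")
        g = read_chrom_sizes(p)
        assert g.chromosomes == (("chr1", 1000), ("chr2", 800))


class TestAlgebraExamples:
    def test_merge_overlapping_and_abutting(self, toy_genome):
        assert as_tuples(merge(iset(toy_genome, [("chr1", 0, 100), ("chr1", 50, 150)]))) == [
            ("chr1", 0, 150)
        ]
        # half-open convention: [0,100) and [100,200) are contiguous
        assert as_tuples(merge(iset(toy_genome, [("chr1", 0, 100), ("chr1", 100, 200)]))) == [
            ("chr1", 0, 200)
        ]

    def test_intersect(self, toy_genome):
        a = iset(toy_genome, [("chr1", 0, 100)])
        b = iset(toy_genome, [("chr1", 50, 150)])
        assert as_tuples(intersect(a, b)) == [("chr1", 50, 100)]
        assert len(intersect(a, iset(toy_genome, [("chr2", 0, 100)]))) == 0

    def test_intersect_genome_mismatch(self, toy_genome):
        other = Genome([("chr1", 1000)])
        with pytest.raises(ValueError, match="different genomes"):
            intersect(iset(toy_genome, []), IntervalSet(other, []))

    def test_subtract_control(self, toy_genome):
        peaks = iset(toy_genome, [("chr1", 0, 100), ("chr1", 200, 300)])
        control = iset(toy_genome, [("chr1", 250, 260)])
        assert as_tuples(subtract_control(peaks, control)) == [("chr1", 0, 100)]
        assert subtract_control(peaks, iset(toy_genome, [])) == peaks
        whole = iset(toy_genome, [("chr1", 0, 1000), ("chr2", 0, 800)])
        assert len(subtract_control(peaks, whole)) == 0
        with pytest.raises(ValueError):
            subtract_control(peaks, control, min_overlap_bp=0)

    def test_consensus_union(self, toy_genome):
        rep1 = iset(toy_genome, [("chr1", 0, 100), ("chr1", 200, 300)])
        rep2 = iset(toy_genome, [("chr1", 50, 150), ("chr1", 400, 500)])
        assert as_tuples(consensus_union(rep1, rep2)) == [("chr1", 0, 150)]
        same = iset(toy_genome, [("chr1", 10, 20)])
        assert as_tuples(consensus_union(same, same)) == [("chr1", 10, 20)]
        disjoint = iset(toy_genome, [("chr2", 0, 50)])
        assert len(consensus_union(rep1, disjoint)) == 0

    def test_consensus_modes(self, toy_genome):
        rep1 = iset(toy_genome, [("chr1", 0, 100)])
        rep2 = iset(toy_genome, [("chr1", 50, 150)])
        assert as_tuples(consensus_union(rep1, rep2, mode="intersection")) == [
            ("chr1", 50, 100)
        ]
        assert as_tuples(consensus_union(rep1, rep2, mode="rep1")) == [("chr1", 0, 100)]
        assert as_tuples(consensus_union(rep1, rep2, mode="rep2")) == [("chr1", 50, 150)]

    def test_overlap_counts(self, toy_genome):
        q = iset(toy_genome, [("chr1", 0, 10), ("chr1", 100, 110), ("chr2", 0, 10)])
        ref = iset(toy_genome, [("chr1", 5, 8)])
        assert overlap_counts(q, ref) == (1, 3)
        assert overlap_counts(q, q) == (3, 3)

    def test_coverage_fraction(self, kb10_genome):
        regions = iset(kb10_genome, [("chr1", 0, 1500), ("chr1", 8000, 8500)])
        assert coverage_fraction(regions, kb10_genome) == pytest.approx(0.2)
        assert coverage_fraction(iset(kb10_genome, []), kb10_genome) == 0.0


@st.composite
def interval_sets(draw):
    """A random genome of 1-3 small chromosomes and two interval sets on it."""
    n_chrom = draw(st.integers(1, 3))
    lengths = [draw(st.integers(50, 2000)) for _ in range(n_chrom)]
    genome = Genome([(f"chr{i+1}", l) for i, l in enumerate(lengths)])

    def one_set():
        n = draw(st.integers(0, 15))
        ivs = []
        for _ in range(n):
            ci = draw(st.integers(0, n_chrom - 1))
            clen = lengths[ci]
            start = draw(st.integers(0, clen - 1))
            end = draw(st.integers(start + 1, clen))
            ivs.append(GenomicInterval(f"chr{ci+1}", start, end))
        return IntervalSet(genome, ivs)

    return genome, one_set(), one_set()


class TestAlgebraProperties:
    @settings(max_examples=150, derandomize=True, deadline=None)
    @given(interval_sets())
    def test_merge_and_intersect_match_perbase_oracle(self, gab):
        genome, a, b = gab
        assert as_tuples(merge(a)) == perbase_to_intervals(genome, perbase(genome, a))
        expect = {
            c: perbase(genome, a)[c] & perbase(genome, b)[c] for c in genome.names
        }
        assert as_tuples(intersect(a, b)) == perbase_to_intervals(genome, expect)
        # commutativity at base level
        assert as_tuples(intersect(a, b)) == as_tuples(intersect(b, a))
        # merge idempotent
        assert merge(merge(a)) == merge(a)

    @settings(max_examples=150, derandomize=True, deadline=None)
    @given(interval_sets())
    def test_subtract_and_consensus_match_bruteforce(self, gab):
        genome, a, b = gab
        ctrl = perbase(genome, b)
        keep = [
            iv for iv in a if not ctrl[iv.chrom][iv.start : iv.end].any()
        ]
        assert as_tuples(subtract_control(a, b)) == as_tuples(
            IntervalSet(genome, keep)
        )
        assert as_tuples(consensus_union(a, b)) == oracle_consensus_union(genome, a, b)
        # symmetry of the consensus operator
        assert as_tuples(consensus_union(a, b)) == as_tuples(consensus_union(b, a))

    @settings(max_examples=80, derandomize=True, deadline=None)
    @given(interval_sets())
    def test_subtract_identities(self, gab):
        genome, a, _ = gab
        assert subtract_control(a, IntervalSet(genome, [])) == a
        ma = merge(a)
        assert len(subtract_control(ma, ma)) == 0
        assert consensus_union(a, a) == merge(a)

    def test_merge_200_random_vs_oracle(self):
        genome = Genome([("chr1", 10_000)])
        rng = np.random.default_rng(7)
        a = random_interval_set(rng, genome, 200, max_len=300)
        assert as_tuples(merge(a)) == perbase_to_intervals(genome, perbase(genome, a))
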