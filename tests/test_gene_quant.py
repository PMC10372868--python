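"""Tests for annotation parsing, read-to-gene assignment, counting and TPM."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from dpcoa_tagseq.gene_quant import (
    AnnotationError,
    Assignment,
    GeneCountTable,
    GeneIndex,
    GeneModel,
    assign_read,
    build_count_table,
    count_from_assignments,
    count_genes,
    five_prime_profile,
    load_annotation,
    merge_intervals,
    profile_from_positions,
    tpm_normalize,
    write_gtf,
)

MILLION = 1_000_000


def make_sam(path, contigs, records):
    """Write a minimal SAM file.

    records: (qname, flag, chrom, pos1, cigar) tuples; sequences are
    omitted ('*') since only reference blocks matter for assignment.
    """
    lines = ["@HD\tVN:1.6\tSO:unknown"]
    for name, length in contigs.items():
        lines.append(f"@SQ\tSN:{name}\tLN:{length}")
    for qname, flag, chrom, pos1, cigar in records:
        lines.append(
            f"{qname}\t{flag}\t{chrom}\t{pos1}\t60\t{cigar}\t*\t0\t0\t*\t*"
        )
    path.write_text("\n".join(lines) + "\n")
    return path


TOY_GTF = """\
chr1\ttoy\tgene\t101\t200\t.\t+\t.\tgene_id "gA"; gene_biotype "protein_coding";
chr1\ttoy\texon\t101\t150\t.\t+\t.\tgene_id "gA";
chr1\ttoy\texon\t141\t180\t.\t+\t.\tgene_id "gA";
chr1\ttoy\texon\t191\t200\t.\t+\t.\tgene_id "gA";
chr1\ttoy\tgene\t301\t400\t.\t-\t.\tgene_id "gB"; gene_biotype "lncRNA";
chr1\ttoy\texon\t301\t400\t.\t-\t.\tgene_id "gB";
chr2\ttoy\tgene\t1\t500\t.\t+\t.\tgene_id "gC";
"""


@pytest.fixture()
def toy_models(tmp_path):
    gtf = tmp_path / "toy.gtf"
    gtf.write_text(TOY_GTF)
    with pytest.warns(UserWarning, match="no exon"):
        return {m.gene_id: m for m in load_annotation(gtf)}


class TestLoadAnnotation:
    def test_coordinate_convention_and_merge(self, toy_models):
        # 1-based closed GTF -> 0-based half-open; overlapping exons union
        gA = toy_models["gA"]
        assert gA.exons == ((100, 180), (190, 200))
        assert gA.strand == "+"
        assert gA.biotype == "coding"

    def test_three_gene_fixture(self, toy_models):
        assert set(toy_models) == {"gA", "gB", "gC"}
        assert toy_models["gB"].exons == ((300, 400),)
        assert toy_models["gB"].biotype == "noncoding"

    def test_gene_without_exons_synthesized(self, toy_models):
        assert toy_models["gC"].exons == ((0, 500),)

    def test_unparseable_line_names_line_number(self, tmp_path):
        gtf = tmp_path / "bad.gtf"
        gtf.write_text(TOY_GTF + "chr1\ttoy\tgene\tnotanumber\t10\t.\t+\t.\tx\n")
        with pytest.raises(AnnotationError, match=":8"):
            load_annotation(gtf)

    def test_gtf_roundtrip(self, toy_models, tmp_path):
        out = tmp_path / "rt.gtf"
        write_gtf(toy_models.values(), out)
        back = {m.gene_id: m for m in load_annotation(out)}
        assert {g: m.exons for g, m in back.items()} == {
            g: m.exons for g, m in toy_models.items()
        }


def test_merge_intervals_examples():
    assert merge_intervals([(100, 150), (140, 180)]) == [(100, 180)]
    assert merge_intervals([(5, 6), (1, 2)]) == [(1, 2), (5, 6)]
    with pytest.raises(ValueError):
        merge_intervals([(10, 10)])


@pytest.fixture()
def overlap_index():
    models = [
        GeneModel("left", "chr1", "+", ((1000, 2000),)),
        GeneModel("right", "chr1", "+", ((1880, 3000),)),
        GeneModel("minus", "chr1", "-", ((1000, 2000),)),
    ]
    return GeneIndex(models)


class TestAssignRead:
    def _read(self, tmp_path, qname, flag, chrom, pos1, cigar, index):
        import pysam

        sam = make_sam(
            tmp_path / "one.sam", {"chr1": 10_000}, [(qname, flag, chrom, pos1, cigar)]
        )
        with pysam.AlignmentFile(str(sam), check_sq=False) as af:
            (aln,) = list(af)
        return assign_read(aln, index)

    def test_unique_containment(self, tmp_path, overlap_index):
        res = self._read(tmp_path, "r", 0, "chr1", 1101, "100M", overlap_index)
        assert res == Assignment("assigned", "left")

    def test_zero_overlap_unassigned(self, tmp_path, overlap_index):
        res = self._read(tmp_path, "r", 0, "chr1", 5001, "100M", overlap_index)
        assert res.status == "unassigned"

    def test_largest_overlap_wins(self, tmp_path, overlap_index):
        # spans [1759, 1999): 120 bp in `left`+`right` overlap zone?
        # alignment 1760..1960 (0-based 1759..1959): left gets 200-ish,
        # use a read overlapping left by 120 and right by 80
        res = self._read(tmp_path, "r", 0, "chr1", 1881, "200M", overlap_index)
        # 0-based [1880, 2080): left overlap 120, right overlap 200 -> right
        assert res == Assignment("assigned", "right")
        res = self._read(tmp_path, "r", 0, "chr1", 1801, "160M", overlap_index)
        # [1800, 1960): left 200? no: left covers to 2000 -> overlap 160;
        # right starts 1880 -> overlap 80 -> left wins
        assert res == Assignment("assigned", "left")

    def test_exact_tie_is_ambiguous(self, tmp_path, overlap_index):
        # [1900, 1960): 60 bp inside both left and right
        res = self._read(tmp_path, "r", 0, "chr1", 1901, "60M", overlap_index)
        assert res.status == "ambiguous"

    def test_strand_requirement(self, tmp_path, overlap_index):
        res = self._read(tmp_path, "r", 16, "chr1", 1101, "100M", overlap_index)
        assert res == Assignment("assigned", "minus")

    def test_spliced_alignment_counts_block_overlap(self, tmp_path, overlap_index):
        # 50M 5000N 50M: second block lands outside any gene
        res = self._read(tmp_path, "r", 0, "chr1", 1101, "50M5000N50M", overlap_index)
        assert res == Assignment("assigned", "left")


class TestCountGenes:
    @pytest.fixture()
    def single_gene_index(self):
        return GeneIndex([GeneModel("G", "chr1", "+", ((0, 5000),))])

    def test_constructed_split(self, tmp_path, single_gene_index):
        records = [(f"t{i}", 0, "chr1", 1, "100M") for i in range(30)]
        records += [(f"u{i}", 0, "chr1", 1, "100M") for i in range(70)]
        sam = make_sam(tmp_path / "s.sam", {"chr1": 10_000}, records)
        calls = {f"t{i}": True for i in range(30)} | {f"u{i}": False for i in range(70)}
        res = count_genes(sam, single_gene_index, calls, "s1")
        assert res.tagged["G"] == 30
        assert res.untagged["G"] == 70
        assert res.n_assigned == 100

    def test_empty_sam(self, tmp_path, single_gene_index):
        sam = make_sam(tmp_path / "e.sam", {"chr1": 10_000}, [])
        res = count_genes(sam, single_gene_index, {}, "s1")
        assert res.tagged.sum() == 0 and res.untagged.sum() == 0

    def test_missing_call_counted_untagged_with_warning(self, tmp_path, single_gene_index):
        sam = make_sam(tmp_path / "m.sam", {"chr1": 10_000}, [("x", 0, "chr1", 1, "50M")])
        with pytest.warns(UserWarning, match="missing from TagCall"):
            res = count_genes(sam, single_gene_index, {}, "s1")
        assert res.untagged["G"] == 1

    def test_order_independence(self, tmp_path, single_gene_index):
        records = [(f"r{i}", 0, "chr1", 1 + 10 * i, "100M") for i in range(20)]
        calls = {f"r{i}": i % 2 == 0 for i in range(20)}
        a = count_genes(
            make_sam(tmp_path / "a.sam", {"chr1": 10_000}, records),
            single_gene_index, calls, "s",
        )
        b = count_genes(
            make_sam(tmp_path / "b.sam", {"chr1": 10_000}, records[::-1]),
            single_gene_index, calls, "s",
        )
        assert a.tagged.equals(b.tagged) and a.untagged.equals(b.untagged)

    def test_secondary_and_unmapped_skipped(self, tmp_path, single_gene_index):
        records = [
            ("p", 0, "chr1", 1, "100M"),
            ("sec", 256, "chr1", 1, "100M"),
            ("sup", 2048, "chr1", 1, "100M"),
            ("unm", 4, "chr1", 1, "*"),
        ]
        sam = make_sam(tmp_path / "f.sam", {"chr1": 10_000}, records)
        res = count_genes(sam, single_gene_index, {"p": True}, "s")
        assert res.n_primary == 1

    def test_conservation_assigned_plus_rest(self, tmp_path, overlap_index):
        records = [
            ("in", 0, "chr1", 1101, "100M"),
            ("tie", 0, "chr1", 1901, "60M"),
            ("out", 0, "chr1", 5001, "100M"),
        ]
        sam = make_sam(tmp_path / "c.sam", {"chr1": 10_000}, records)
        res = count_genes(sam, overlap_index, {"in": False, "tie": False, "out": False}, "s")
        assert (res.n_assigned, res.n_ambiguous, res.n_unassigned) == (1, 1, 1)


class TestTpmNormalize:
    def test_direct_arithmetic(self):
        counts = pd.DataFrame({"s1": [10, 30, 60]}, index=["A", "B", "C"])
        t = tpm_normalize(GeneCountTable(counts=counts))
        assert list(t.tpm["s1"]) == [100_000, 300_000, 600_000]

    def test_single_gene_is_million(self):
        counts = pd.DataFrame({"s1": [42]}, index=["A"])
        t = tpm_normalize(GeneCountTable(counts=counts))
        assert t.tpm.loc["A", "s1"] == MILLION

    def test_column_sums_conserved_random(self):
        rng = np.random.default_rng(5)
        counts = pd.DataFrame(
            rng.integers(0, 1000, size=(200, 5)),
            index=[f"g{i}" for i in range(200)],
            columns=[f"s{i}" for i in range(5)],
        )
        t = tpm_normalize(GeneCountTable(counts=counts))
        assert np.allclose(t.tpm.sum(axis=0), MILLION, rtol=1e-6)

    def test_zero_sample_warns_and_zeroes(self):
        counts = pd.DataFrame({"s1": [0, 0]}, index=["A", "B"])
        with pytest.warns(UserWarning, match="zero counted"):
            t = tpm_normalize(GeneCountTable(counts=counts))
        assert (t.tpm["s1"] == 0).all()

    def test_negative_counts_rejected(self):
        counts = pd.DataFrame({"s1": [-1]}, index=["A"])
        with pytest.raises(ValueError):
            GeneCountTable(counts=counts)

    def test_external_run_totals(self):
        # tagged reads are a slice of the run; denominator is the run total
        counts = pd.DataFrame({"s1": [5, 15]}, index=["A", "B"])
        t = tpm_normalize(GeneCountTable(counts=counts), totals=pd.Series({"s1": 1000}))
        assert t.tpm.loc["A", "s1"] == 5_000
        with pytest.raises(ValueError, match="totals"):
            tpm_normalize(GeneCountTable(counts=counts), totals=pd.Series({"s1": 10}))


class TestFivePrimeProfile:
    def test_identical_distributions_d_zero(self):
        pos = [100] * 10 + [105] * 10
        prof = profile_from_positions("g", pos, pos)
        assert prof.ks_d == 0.0

    def test_disjoint_supports_d_one(self):
        prof = profile_from_positions("g", [100] * 20, [150 + i for i in range(20)])
        assert prof.ks_d == 1.0

    def test_min_reads_gate(self):
        prof = profile_from_positions("g", [1, 2], [1, 2, 3, 4, 5], min_reads=5)
        assert prof.ks_d is None

    def test_strand_aware_extraction_from_sam(self, tmp_path):
        index = GeneIndex([GeneModel("G", "chr1", "-", ((0, 5000),))])
        # reverse-strand read: 5' end is the rightmost aligned base
        sam = make_sam(
            tmp_path / "p.sam",
            {"chr1": 10_000},
            [(f"r{i}", 16, "chr1", 1001, "100M") for i in range(10)],
        )
        calls = {f"r{i}": i < 5 for i in range(10)}
        prof = five_prime_profile(sam, calls, index.models["G"], index, min_reads=3)
        assert list(prof.tagged.index) == [1099]
        assert prof.ks_d == 0.0

    def test_same_start_with_truncation_noise_rarely_flags(self):
        """5'-loss jitter applied to both classes stays under D=0.25."""
        rng = np.random.default_rng(0)
        ok = 0
        for _ in range(20):
            start = 500
            t = start + rng.geometric(1 / 50, size=200) * (rng.random(200) < 0.2)
            u = start + rng.geometric(1 / 50, size=200) * (rng.random(200) < 0.2)
            prof = profile_from_positions("g", t, u)
            ok += prof.ks_d < 0.25
        assert ok >= 19


def test_count_from_assignments_matches_truth():
    index = GeneIndex(
        [GeneModel("A", "c1", "+", ((0, 100),)), GeneModel("B", "c2", "+", ((0, 100),))]
    )
    assignments = {"r1": "A", "r2": "A", "r3": "B", "r4": "missing"}
    calls = {"r1": True, "r2": False, "r3": True}
    res = count_from_assignments(assignments, index, calls, "s")
    assert res.tagged["A"] == 1 and res.untagged["A"] == 1 and res.tagged["B"] == 1
    assert res.n_unassigned == 1


def test_build_count_table_multi_sample_alignment():
    index = GeneIndex([GeneModel("A", "c", "+", ((0, 10),))])
    r1 = count_from_assignments({"x": "A"}, index, {"x": True}, "s1")
    r2 = count_from_assignments({"y": "A", "z": "A"}, index, {"y": True, "z": True}, "s2")
    table = build_count_table([r1, r2], "tagged")
    assert table.counts.loc["A", "s1"] == 1 and table.counts.loc["A", "s2"] == 2
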