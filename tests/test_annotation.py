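import pytest

from slamkit.annotation import (
    CompatOptions,
    GeneIndex,
    GtfParseError,
    assign_read,
    load_annotation,
    merge_intervals,
)

from conftest import make_read


def write_gtf(path, rows):
    with open(path, "w") as fh:
        for chrom, feat, start, end, strand, attrs in rows:
            fh.write(f"{chrom}\tsrc\t{feat}\t{start}\t{end}\t.\t{strand}\t.\t{attrs}\n")
    return path


EX = 'gene_id "g1"; transcript_id "g1.t{t}";'


class TestLoadAnnotation:
    def test_single_transcript_union_and_introns(self, tmp_path):
        gtf = write_gtf(
            tmp_path / "a.gtf",
            [
                ("chr1", "exon", 1, 100, "+", EX.format(t=1)),
                ("chr1", "exon", 201, 300, "+", EX.format(t=1)),
            ],
        )
        genes = load_annotation(gtf)
        g = genes["g1"]
        assert g.union_exons == [(0, 100), (200, 300)]
        assert g.introns() == [(100, 200)]
        assert g.junctions() == {(100, 200)}

    def test_two_transcripts_union_merges(self, tmp_path):
        gtf = write_gtf(
            tmp_path / "a.gtf",
            [
                ("chr1", "exon", 1, 100, "+", EX.format(t=1)),
                ("chr1", "exon", 51, 150, "+", EX.format(t=2)),
            ],
        )
        assert load_annotation(gtf)["g1"].union_exons == [(0, 150)]

    def test_empty_gtf(self, tmp_path):
        (tmp_path / "e.gtf").write_text("")
        assert load_annotation(tmp_path / "e.gtf") == {}

    @pytest.mark.parametrize(
        "attrs,msg",
        [
            ('transcript_id "t1";', "gene_id"),
            ('gene_id "g1";', "transcript_id"),
        ],
    )
    def test_missing_attribute_names_line(self, tmp_path, attrs, msg):
        gtf = write_gtf(tmp_path / "a.gtf", [("chr1", "exon", 1, 100, "+", attrs)])
        with pytest.raises(GtfParseError, match=r"line 1.*" + msg):
            load_annotation(gtf)

    def test_inverted_coordinates_rejected(self, tmp_path):
        gtf = write_gtf(tmp_path / "a.gtf", [("chr1", "exon", 100, 50, "+", EX.format(t=1))])
        with pytest.raises(GtfParseError, match="line 1"):
            load_annotation(gtf)

    def test_transcript_order_invariance(self, tmp_path):
        rows = [
            ("chr1", "exon", 1, 100, "+", EX.format(t=1)),
            ("chr1", "exon", 201, 300, "+", EX.format(t=1)),
            ("chr1", "exon", 51, 250, "+", EX.format(t=2)),
        ]
        g_fwd = load_annotation(write_gtf(tmp_path / "f.gtf", rows))["g1"]
        g_rev = load_annotation(write_gtf(tmp_path / "r.gtf", rows[::-1]))["g1"]
        assert g_fwd.union_exons == g_rev.union_exons
        assert g_fwd.introns() == g_rev.introns()


def test_merge_intervals_properties():
    merged = merge_intervals([(5, 9), (0, 3), (2, 4), (9, 12)])
    assert merged == [(0, 4), (5, 12)]
    assert all(s < e for s, e in merged)
    assert all(b[0] > a[1] for a, b in zip(merged, merged[1:]))


@pytest.fixture
def two_gene_index(tmp_path):
    gtf = write_gtf(
        tmp_path / "g.gtf",
        [
            ("chr1", "exon", 1, 100, "+", 'gene_id "gA"; transcript_id "gA.t1";'),
            ("chr1", "exon", 201, 300, "+", 'gene_id "gA"; transcript_id "gA.t1";'),
            ("chr1", "exon", 51, 150, "+", 'gene_id "gB"; transcript_id "gB.t1";'),
            ("chr1", "exon", 401, 500, "-", 'gene_id "gC"; transcript_id "gC.t1";'),
        ],
    )
    return GeneIndex(load_annotation(gtf))


GEDI = CompatOptions().resolve("gedi")
DEFAULT = CompatOptions().resolve("none")


class TestAssignRead:
    def test_exonic_sense_default(self, two_gene_index):
        read = make_read(blocks=(((10, 40), 0),), sequence="A" * 30)
        (asg,) = assign_read(read, two_gene_index, DEFAULT)
        assert (asg.gene_id, asg.category, asg.weight) == ("gA", "exonic", 1.0)

    def test_antisense_read_unassigned(self, two_gene_index):
        read = make_read(strand="-", blocks=(((10, 40), 0),), sequence="A" * 30)
        (asg,) = assign_read(read, two_gene_index, DEFAULT)
        assert asg.category == "unassigned"

    def test_antisense_protocol_flag_inverts(self, two_gene_index):
        read = make_read(strand="-", blocks=(((10, 40), 0),), sequence="A" * 30)
        (asg,) = assign_read(read, two_gene_index, DEFAULT, strandedness="antisense")
        assert asg.category == "exonic" and asg.gene_id == "gA"

    def test_multi_gene_ambiguous_default(self, two_gene_index):
        read = make_read(blocks=(((60, 90), 0),), sequence="A" * 30)
        asgs = assign_read(read, two_gene_index, DEFAULT)
        assert {a.category for a in asgs} == {"ambiguous"}
        assert sum(a.weight for a in asgs) == 0.0

    def test_compat_weighting_splits_weight(self, two_gene_index):
        read = make_read(blocks=(((60, 90), 0),), sequence="A" * 30, n_alignments=2)
        asgs = assign_read(read, two_gene_index, GEDI)
        assert sorted(a.gene_id for a in asgs) == ["gA", "gB"]
        assert all(a.weight == pytest.approx(0.25) for a in asgs)
        # total weight over genes equals 1 / n_alignments
        assert sum(a.weight for a in asgs) == pytest.approx(0.5)

    def test_compat_intronic_unspliced(self, two_gene_index):
        read = make_read(blocks=(((160, 190), 0),), sequence="A" * 30)
        assert assign_read(read, two_gene_index, DEFAULT)[0].category == "unassigned"
        (asg,) = assign_read(read, two_gene_index, GEDI)
        assert (asg.gene_id, asg.category) == ("gA", "intronic")

    def test_compat_lenient_overlap_with_junction_concordance(self, two_gene_index):
        # spliced read over gA's junction whose 3' block runs past the exon
        # end (120 of 140 bases exonic, >= 50%): rejected by the strict
        # containment rule, accepted leniently since the junction matches gA
        read = make_read(
            blocks=(((80, 100), 0), ((200, 320), 20)), sequence="A" * 140
        )
        read_bad = make_read(
            blocks=(((80, 100), 0), ((210, 330), 20)), sequence="A" * 140
        )
        lenient_only = CompatOptions(intronic=False, weighting=False).resolve("gedi")
        assert assign_read(read, two_gene_index, DEFAULT)[0].category == "unassigned"
        (asg,) = assign_read(read, two_gene_index, lenient_only)
        assert (asg.gene_id, asg.category) == ("gA", "exonic")
        # discordant junction: rejected even leniently
        assert assign_read(read_bad, two_gene_index, lenient_only)[0].category == "unassigned"

    def test_default_acceptance_is_subset_of_compat(self, two_gene_index):
        import numpy as np

        rng = np.random.default_rng(5)
        for _ in range(200):
            start = int(rng.integers(0, 480))
            length = int(rng.integers(10, 60))
            strand = "+" if rng.random() < 0.5 else "-"
            read = make_read(
                strand=strand, blocks=(((start, start + length), 0),), sequence="A" * length
            )
            default_genes = {
                a.gene_id for a in assign_read(read, two_gene_index, DEFAULT)
                if a.category == "exonic" and a.weight > 0
            }
            compat_genes = {
                a.gene_id for a in assign_read(read, two_gene_index, GEDI) if a.weight > 0
            }
            assert default_genes <= compat_genes
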