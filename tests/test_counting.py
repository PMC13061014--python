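import numpy as np
import pandas as pd
import pytest

from slamkit.counting import (
    ConversionProfile,
    ReadConversionCount,
    SiteTable,
    aggregate_gene_counts,
    count_read,
    resolve_pair_overlap,
)
from slamkit.snp import SnpMask

from conftest import make_read
from oracles import pileup_counts


REF = "TTAAGGCCTT"


class TestCountRead:
    def test_plus_strand_basic(self):
        read = make_read(blocks=(((0, 10), 0),), sequence="TCAAGGCCTT")
        n_t, k = count_read(read, "+", REF, q_floor=0)
        assert (n_t, k) == (4, 1)

    def test_masked_position_excluded_from_both(self):
        read = make_read(blocks=(((0, 10), 0),), sequence="TCAAGGCCTT")
        mask = SnpMask({("chr1", 1)})
        n_t, k = count_read(read, "+", REF, mask=mask, q_floor=0)
        assert (n_t, k) == (3, 0)

    def test_no_sense_T_positions(self):
        read = make_read(blocks=(((2, 8), 2),), sequence="xxAAGGCCxx".replace("x", "A"))
        n_t, k = count_read(read, "+", REF, q_floor=0)
        assert (n_t, k) == (0, 0)

    def test_minus_strand_gene_reference_A_read_G(self):
        # sense T of a minus-strand gene is reference A; conversion shows as G
        ref = "AAGGCC"
        read = make_read(blocks=(((0, 6), 0),), sequence="AGGGCC")
        n_t, k = count_read(read, "-", ref, q_floor=0)
        assert (n_t, k) == (2, 1)

    def test_quality_floor(self):
        read = make_read(
            blocks=(((0, 10), 0),), sequence="TCAAGGCCTT",
            quals=[10] * 10,
        )
        assert count_read(read, "+", REF, q_floor=20) == (0, 0)
        assert count_read(read, "+", REF, q_floor=5) == (4, 1)

    def test_trim_windows_use_sequencing_orientation(self):
        read_fwd = make_read(blocks=(((0, 10), 0),), sequence="TCAAGGCCTT")
        assert count_read(read_fwd, "+", REF, trim5=2, q_floor=0) == (2, 0)
        # reverse alignment: sequencing position p = L-1-qpos, so a 5' trim
        # removes the stored 3' end and the position-1 conversion survives
        read_rev = make_read(strand="-", blocks=(((0, 10), 0),), sequence="TCAAGGCCTT")
        assert count_read(read_rev, "+", REF, trim5=2, q_floor=0) == (2, 1)

    def test_n_bases_excluded(self):
        read = make_read(blocks=(((0, 10), 0),), sequence="TNAAGGCCTT")
        assert count_read(read, "+", REF, q_floor=0) == (3, 0)

    def test_short_reference_window_is_error(self):
        read = make_read(blocks=(((0, 10), 0),), sequence="TCAAGGCCTT")
        with pytest.raises(ValueError, match="reference window"):
            count_read(read, "+", "TTA", q_floor=0)

    def test_site_and_profile_increments_consistent(self):
        st = SiteTable()
        prof = ConversionProfile(n_chunks=2)
        read = make_read(blocks=(((0, 10), 0),), sequence="TCAAGGCCTT")
        count_read(read, "+", REF, q_floor=0, site_table=st, profile=prof, chunk=1)
        assert st.tc_count("chr1", 1) == 1
        assert st.coverage("chr1", 0) == 1
        assert prof.total_t_cov().sum() == 4
        assert prof.total_tc().sum() == 1
        # chunked sums equal totals
        assert (prof.t_cov.sum(axis=0) == prof.total_t_cov()).all()


class TestPairOverlap:
    def make_pair(self, seq1, seq2, start2, quals1=None, quals2=None):
        m1 = make_read("p/1", blocks=(((0, len(seq1)), 0),), sequence=seq1, quals=quals1, paired=True)
        m2 = make_read(
            "p/2", blocks=(((start2, start2 + len(seq2)), 0),), sequence=seq2,
            quals=quals2, paired=True, first=False,
        )
        return m1, m2

    def test_concordant_overlap_counted_once(self):
        m1, m2 = self.make_pair("TCAAGGCCTT", "CCTTAA", 6)
        a1, a2 = resolve_pair_overlap(m1, m2)
        st = SiteTable()
        n1, k1 = count_read(m1, "+", REF + "AA", q_floor=0, allowed_qpos=a1, site_table=st)
        n2, k2 = count_read(m2, "+", REF + "AA", q_floor=0, allowed_qpos=a2, site_table=st)
        # overlap covers positions 6-9 (ref CCTT): the two Ts count once
        assert n1 + n2 == 4
        assert st.coverage("chr1", 8) == 1 and st.coverage("chr1", 9) == 1

    def test_drop_discordant_excludes_position(self):
        # position 8: mate1 reads C (conversion), mate2 reads T
        m1, m2 = self.make_pair("TCAAGGCCCT", "CCTTAA", 6)
        a1, a2 = resolve_pair_overlap(m1, m2, policy="drop_discordant")
        n1, k1 = count_read(m1, "+", REF + "AA", q_floor=0, allowed_qpos=a1)
        n2, k2 = count_read(m2, "+", REF + "AA", q_floor=0, allowed_qpos=a2)
        # rpos 8 dropped from both; mate1's own positions 0/1 still count
        assert n1 + n2 == 3 and k1 + k2 == 1

    def test_count_once_higher_quality_wins(self):
        m1, m2 = self.make_pair(
            "TCAAGGCCCT", "CCTTAA", 6, quals1=[20] * 10, quals2=[40] * 6
        )
        a1, a2 = resolve_pair_overlap(m1, m2, policy="count_once")
        n1, k1 = count_read(m1, "+", REF + "AA", q_floor=0, allowed_qpos=a1)
        n2, k2 = count_read(m2, "+", REF + "AA", q_floor=0, allowed_qpos=a2)
        # mate2's higher-quality T wins at rpos 8: no conversion there, but
        # the position still counts toward n_T via mate2
        assert k1 + k2 == 1 and n1 + n2 == 4

    def test_disjoint_mates_union(self):
        m1, m2 = self.make_pair("TCAAG", "CCTTA", 5)
        a1, a2 = resolve_pair_overlap(m1, m2)
        assert a1 == set(range(5)) and a2 == set(range(5))


class TestAggregate:
    def test_plain_sums(self):
        rcs = [
            ReadConversionCount("r1", "g", 10, 1, 1.0),
            ReadConversionCount("r2", "g", 8, 0, 1.0),
        ]
        per_gene, low = aggregate_gene_counts(rcs, min_reads=20)
        g = per_gene["g"]
        assert (g.K, g.N_T, g.read_count) == (1.0, 18.0, 2.0)
        assert "g" in low

    def test_weighted_sums(self):
        rcs = [
            ReadConversionCount("r1", "g", 10, 1, 0.5),
            ReadConversionCount("r2", "g", 8, 0, 0.5),
        ]
        g = aggregate_gene_counts(rcs, min_reads=1)[0]["g"]
        assert (g.K, g.N_T, g.read_count) == (0.5, 9.0, 1.0)

    def test_empty_input(self):
        per_gene, low = aggregate_gene_counts([], min_reads=1)
        assert per_gene == {} and low == set()


class TestInvariantsOnSimulatedData:
    def test_oracle_equivalence_and_conservation(self, tiny_dataset):
        """Package counts match an independent pileup walker read-for-read,
        and summed conversions equal the site-table totals."""
        from slamkit import PipelineOptions, run_quant

        truth_reads = tiny_dataset["truth"]["reads"]
        truth_genes = tiny_dataset["truth"]["genes"]
        gene_of_read = dict(zip(truth_reads.read_id, truth_reads.gene_id))
        strand_of_gene = dict(zip(truth_genes.gene_id, truth_genes.strand))

        opts = PipelineOptions(
            bam=[str(tiny_dataset["sam"])], fasta=str(tiny_dataset["fasta"]),
            gtf=str(tiny_dataset["gtf"]), out_prefix=str(tiny_dataset["sam"].parent / "o" / "x"),
            min_base_qual=0, qc_report=False,
        )
        res = run_quant(opts)
        oracle = pileup_counts(
            tiny_dataset["sam"], tiny_dataset["fasta"], gene_of_read, strand_of_gene
        )
        ours = {rc.read_id: (rc.n_T, rc.k) for rc in res.read_counts}
        assert ours == {rid: oracle[rid] for rid in ours}
        # conservation: sum of per-read k equals site-table tc total
        assert sum(rc.k for rc in res.read_counts) == res.site_table.totals()["tc"]

    def test_mask_monotonicity(self, tiny_dataset):
        """Enlarging the SNP mask never increases any gene's K or N_T."""
        from slamkit import PipelineOptions, run_quant

        base = PipelineOptions(
            bam=[str(tiny_dataset["sam"])], fasta=str(tiny_dataset["fasta"]),
            gtf=str(tiny_dataset["gtf"]),
            out_prefix=str(tiny_dataset["sam"].parent / "m0" / "x"),
            min_base_qual=0, qc_report=False,
        )
        res0 = run_quant(base)
        snps = tiny_dataset["truth"]["snps"]
        bed = tiny_dataset["sam"].parent / "mask.bed"
        bed.write_text(
            "".join(f"{c}\t{p}\t{p + 1}\n" for c, p in zip(snps.chrom, snps.pos))
        )
        import dataclasses

        res1 = run_quant(
            dataclasses.replace(
                base, snp_bed=str(bed),
                out_prefix=str(tiny_dataset["sam"].parent / "m1" / "x"),
            )
        )
        k0 = {rc.read_id: rc.k for rc in res0.read_counts}
        n0 = {rc.read_id: rc.n_T for rc in res0.read_counts}
        for rc in res1.read_counts:
            assert rc.k <= k0[rc.read_id]
            assert rc.n_T <= n0[rc.read_id]
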