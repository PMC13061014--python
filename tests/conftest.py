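import sys
from pathlib import Path

import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from slamkit import SimConfig
from slamkit.alignments import AlignedReadRecord
from slamkit.simulate import write_dataset


def make_read(
    read_id="r1",
    chrom="chr1",
    strand="+",
    blocks=(((0, 10), 0),),
    sequence="A" * 10,
    quals=None,
    n_alignments=1,
    paired=False,
    first=True,
):
    blocks = [((int(s), int(e)), int(q)) for (s, e), q in blocks]
    return AlignedReadRecord(
        read_id=read_id,
        chrom=chrom,
        alignment_strand=strand,
        blocks=blocks,
        sequence=sequence,
        base_qualities=list(quals) if quals is not None else [40] * len(sequence),
        is_paired=paired,
        is_first_mate=first,
        n_alignments=n_alignments,
    )


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory):
    """Small simulated benchmark: 5 genes, 60 reads each, 10 planted SNPs."""
    out = tmp_path_factory.mktemp("tiny_sim")
    cfg = SimConfig(n_genes=5, reads_per_gene=60, snp_sites=10, seed=42)
    paths = write_dataset(cfg, out)
    paths["cfg"] = cfg
    paths["truth"] = {
        key: pd.read_csv(paths[f"truth_{key}"], sep="\t")
        for key in ("genes", "snps", "reads")
    }
    return paths


@pytest.fixture(scope="session")
def flagship_dataset(tmp_path_factory):
    """The reference benchmark scenario: 20 genes x 500 reads, planted SNPs."""
    out = tmp_path_factory.mktemp("flagship_sim")
    cfg = SimConfig(seed=13, snp_sites=30)
    paths = write_dataset(cfg, out)
    paths["cfg"] = cfg
    paths["truth_genes_df"] = pd.read_csv(paths["truth_genes"], sep="\t")
    return paths
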