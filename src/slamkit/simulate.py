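"""Synthetic SLAM-seq benchmark generator.

Builds a toy multi-gene genome with exon/intron structure, draws reads from
per-gene new/old fractions (new reads convert sense-strand T at ``p_new``,
pre-existing reads at the background rate ``p_old``), plants genomic T>C SNPs
at heterozygous (0.5) or homozygous (1.0) allele fractions, and optionally
elevates conversion rates inside artifact windows at the read ends. Alignments
are emitted as coordinate-sorted SAM records together with a complete ground
truth (per-gene new fraction, per-site SNP fractions, per-read origin and
substitution events), so the whole quantification stack is testable without
external data.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


class SimConfigError(ValueError):
    """Raised when the requested geometry or rates are infeasible."""


@dataclass
class SimConfig:
    """Study conditions for the synthetic benchmark.

    Defaults follow the reference scenario used throughout the test suite:
    20 genes x 500 reads, 80 bp single-end reads (~20 usable T positions per
    read at uniform base composition), labeled conversion rate 0.05 against a
    background of 0.001, and a uniform sequencing error rate of 1e-3.
    """

    n_genes: int = 20
    gene_length: int = 1000
    exons_per_gene: int = 2
    exon_length: int = 400
    reads_per_gene: int = 500
    read_length: int = 80
    pi_per_gene: list[float] | None = None  # None: drawn uniform(0, 1)
    p_new: float = 0.05
    p_old: float = 0.001
    snp_sites: int = 0
    snp_het_proportion: float = 0.5  # share of planted SNPs that are het (0.5)
    artifact_len5: int = 0
    artifact_len3: int = 0
    artifact_rate: float = 0.0
    base_error_rate: float = 0.001
    paired: bool = False
    fragment_length: int = 120
    minus_strand_fraction: float = 0.5
    gene_spacing: int = 200
    chrom: str = "chr1"
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 <= self.p_old < self.p_new <= 1.0):
            raise SimConfigError("require 0 <= p_old < p_new <= 1")
        if self.artifact_len5 + self.artifact_len3 >= self.read_length / 2 and (
            self.artifact_len5 or self.artifact_len3
        ):
            if self.artifact_len5 >= self.read_length / 2 or self.artifact_len3 >= self.read_length / 2:
                raise SimConfigError("artifact window must be shorter than half the read")
        if self.exons_per_gene < 1:
            raise SimConfigError("need at least one exon per gene")
        if self.exons_per_gene * self.exon_length > self.gene_length:
            raise SimConfigError(
                f"exons ({self.exons_per_gene} x {self.exon_length}) exceed gene span {self.gene_length}"
            )
        if self.exon_length < self.read_length:
            raise SimConfigError("exon_length must be >= read_length for unspliced reads")
        if self.paired and not (self.read_length <= self.fragment_length <= self.exon_length):
            raise SimConfigError("fragment_length must lie in [read_length, exon_length]")
        if self.pi_per_gene is not None and len(self.pi_per_gene) != self.n_genes:
            raise SimConfigError("pi_per_gene length must equal n_genes")


@dataclass
class SimGene:
    gene_id: str
    gene_name: str
    strand: str
    span: tuple[int, int]  # 0-based half-open genomic interval
    exons: list[tuple[int, int]]


@dataclass
class SimRead:
    read_id: str
    gene_id: str
    origin: str  # "new" | "old"
    start: int  # genomic start of the (fragment's) leftmost base
    sense_seq: str
    conversions: list[int]  # sense-orientation offsets with a planted T>C
    errors: list[tuple[int, str]]  # sense-orientation (offset, final base)


@dataclass
class GroundTruth:
    genes: list[dict] = field(default_factory=list)  # gene_id, strand, true_pi, n_reads
    snps: list[dict] = field(default_factory=list)  # chrom, pos, fraction, gene_id
    reads: list[dict] = field(default_factory=list)  # read_id, gene_id, origin, ...


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([seed, stream])


def build_genome(cfg: SimConfig) -> tuple[str, list[SimGene]]:
    """Deterministic toy genome: uniform base composition, genes laid end to
    end with spacing, equally sized exons separated by equal introns."""
    cfg.validate()
    rng = _rng(cfg.seed, 0)
    genes: list[SimGene] = []
    cursor = cfg.gene_spacing
    for g in range(cfg.n_genes):
        start = cursor
        end = start + cfg.gene_length
        e = cfg.exons_per_gene
        if e == 1:
            exons = [(start, start + cfg.exon_length)]
        else:
            gap = (cfg.gene_length - e * cfg.exon_length) // (e - 1)
            exons = []
            pos = start
            for _ in range(e):
                exons.append((pos, pos + cfg.exon_length))
                pos += cfg.exon_length + gap
        strand = "-" if rng.random() < cfg.minus_strand_fraction else "+"
        genes.append(SimGene(f"g{g:03d}", f"GENE{g:03d}", strand, (start, end), exons))
        cursor = end + cfg.gene_spacing
    length = cursor
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])
    return seq, genes


def _plant_snps(cfg: SimConfig, seq: str, genes: list[SimGene], rng: np.random.Generator) -> dict[int, float]:
    """Pick sense-strand T sites inside exons and assign allele fractions."""
    if cfg.snp_sites == 0:
        return {}
    candidates: list[int] = []
    for gene in genes:
        want = "T" if gene.strand == "+" else "A"
        for es, ee in gene.exons:
            for p in range(es, ee):
                if seq[p] == want:
                    candidates.append(p)
    if len(candidates) < cfg.snp_sites:
        raise SimConfigError("not enough exonic T sites to plant the requested SNPs")
    chosen = rng.choice(len(candidates), size=cfg.snp_sites, replace=False)
    n_het = int(round(cfg.snp_sites * cfg.snp_het_proportion))
    fractions = {}
    for i, ci in enumerate(sorted(chosen)):
        fractions[candidates[ci]] = 0.5 if i < n_het else 1.0
    return fractions


def _simulate_fragment(
    cfg: SimConfig,
    seq: str,
    gene: SimGene,
    snps: dict[int, float],
    pi: float,
    rng: np.random.Generator,
    frag_len: int,
) -> tuple[str, int, list[int], str]:
    """Draw one fragment: returns (sense sequence, genomic start, planted
    conversion offsets in sense orientation, origin)."""
    usable = [e for e in gene.exons if e[1] - e[0] >= frag_len]
    weights = np.array([e[1] - e[0] - frag_len + 1 for e in usable], dtype=float)
    ei = rng.choice(len(usable), p=weights / weights.sum())
    es, ee = usable[ei]
    start = int(rng.integers(es, ee - frag_len + 1))
    genomic = seq[start : start + frag_len]
    sense = genomic if gene.strand == "+" else revcomp(genomic)
    origin = "new" if rng.random() < pi else "old"
    p_conv = cfg.p_new if origin == "new" else cfg.p_old
    bases = list(sense)
    conv: list[int] = []
    for off in range(frag_len):
        if bases[off] != "T":
            continue
        gpos = start + off if gene.strand == "+" else start + frag_len - 1 - off
        in5 = off < cfg.artifact_len5
        in3 = off >= frag_len - cfg.artifact_len3
        rate = cfg.artifact_rate if (in5 or in3) else p_conv
        hit = rng.random() < rate
        if not hit and gpos in snps:
            hit = rng.random() < snps[gpos]
        if hit:
            bases[off] = "C"
            conv.append(off)
    return "".join(bases), start, conv, origin


def _apply_errors(cfg: SimConfig, sense: str, rng: np.random.Generator) -> tuple[str, list[tuple[int, str]]]:
    bases = list(sense)
    errors: list[tuple[int, str]] = []
    n = len(bases)
    hits = np.nonzero(rng.random(n) < cfg.base_error_rate)[0]
    for off in hits:
        alts = [b for b in "ACGT" if b != bases[off]]
        bases[off] = alts[int(rng.integers(0, 3))]
        errors.append((int(off), bases[off]))
    return "".join(bases), errors


def simulate_reads(cfg: SimConfig, seq: str, genes: list[SimGene]) -> tuple[list[SimRead], GroundTruth]:
    truth_rng = _rng(cfg.seed, 1)
    rng = _rng(cfg.seed, 2)
    snps = _plant_snps(cfg, seq, genes, truth_rng)
    if cfg.pi_per_gene is not None:
        pis = np.asarray(cfg.pi_per_gene, dtype=float)
    else:
        pis = truth_rng.uniform(0.0, 1.0, size=cfg.n_genes)

    truth = GroundTruth()
    pos_to_gene = {}
    for gene in genes:
        for es, ee in gene.exons:
            pos_to_gene.update({p: gene.gene_id for p in range(es, ee)})
    for pos, frac in sorted(snps.items()):
        truth.snps.append(
            {"chrom": cfg.chrom, "pos": pos, "fraction": frac, "gene_id": pos_to_gene.get(pos, "")}
        )

    reads: list[SimRead] = []
    serial = 0
    frag_len = cfg.fragment_length if cfg.paired else cfg.read_length
    for gi, gene in enumerate(genes):
        n_new = 0
        for _ in range(cfg.reads_per_gene):
            sense, start, conv, origin = _simulate_fragment(
                cfg, seq, gene, snps, float(pis[gi]), rng, frag_len
            )
            n_new += origin == "new"
            rid = f"sim{serial:07d}"
            serial += 1
            if not cfg.paired:
                final, errors = _apply_errors(cfg, sense, rng)
                reads.append(SimRead(rid, gene.gene_id, origin, start, final, conv, errors))
                truth.reads.append(
                    {
                        "read_id": rid,
                        "gene_id": gene.gene_id,
                        "origin": origin,
                        "start": start,
                        "conversions": ",".join(map(str, conv)),
                        "errors": ",".join(f"{o}:{b}" for o, b in errors),
                    }
                )
            else:
                # Mates share the fragment's conversions; errors are per mate.
                L = cfg.read_length
                for mate, m_sense in ((1, sense[:L]), (2, sense[frag_len - L :])):
                    m_conv = (
                        [c for c in conv if c < L]
                        if mate == 1
                        else [c - (frag_len - L) for c in conv if c >= frag_len - L]
                    )
                    final, errors = _apply_errors(cfg, m_sense, rng)
                    if gene.strand == "+":
                        m_start = start if mate == 1 else start + frag_len - L
                    else:
                        m_start = start + frag_len - L if mate == 1 else start
                    reads.append(
                        SimRead(f"{rid}/{mate}", gene.gene_id, origin, m_start, final, m_conv, errors)
                    )
                    truth.reads.append(
                        {
                            "read_id": f"{rid}/{mate}",
                            "gene_id": gene.gene_id,
                            "origin": origin,
                            "start": m_start,
                            "conversions": ",".join(map(str, m_conv)),
                            "errors": ",".join(f"{o}:{b}" for o, b in errors),
                        }
                    )
        truth.genes.append(
            {
                "gene_id": gene.gene_id,
                "strand": gene.strand,
                "true_pi": float(pis[gi]),
                "n_reads": cfg.reads_per_gene,
                "n_new": n_new,
            }
        )
    return reads, truth


def _sam_records(cfg: SimConfig, genes: list[SimGene], reads: list[SimRead]) -> list[tuple[int, str]]:
    strand = {g.gene_id: g.strand for g in genes}
    L = cfg.read_length
    mate_start: dict[tuple[str, str], int] = {}
    if cfg.paired:
        for r in reads:
            qname, mate = r.read_id.rsplit("/", 1)
            mate_start[(qname, mate)] = r.start
    recs = []
    for r in reads:
        minus = strand[r.gene_id] == "-"
        seq = revcomp(r.sense_seq) if minus else r.sense_seq
        if not cfg.paired:
            flag = 16 if minus else 0
            qname = r.read_id
            rnext, pnext, tlen = "*", 0, 0
        else:
            qname, mate = r.read_id.rsplit("/", 1)
            first = mate == "1"
            # Sense-orientation mate 1 maps forward on + genes, reverse on -.
            rev = minus
            flag = 0x1 | 0x2 | (0x10 if rev else 0x20) | (0x40 if first else 0x80)
            other = mate_start[(qname, "2" if first else "1")]
            rnext, pnext = "=", other + 1
            lo = min(r.start, other)
            span = max(r.start, other) + L - lo
            tlen = span if r.start <= other else -span
        recs.append(
            (
                r.start,
                "\t".join(
                    [
                        qname,
                        str(flag),
                        cfg.chrom,
                        str(r.start + 1),
                        "255",
                        f"{len(seq)}M",
                        rnext,
                        str(pnext),
                        str(tlen),
                        seq,
                        "F" * len(seq),
                        "NH:i:1",
                    ]
                ),
            )
        )
    _ = L
    return sorted(recs, key=lambda t: (t[0], t[1]))


def write_dataset(cfg: SimConfig, out_dir: str | Path) -> dict[str, Path]:
    """Generate and write FASTA, GTF, coordinate-sorted SAM, ground-truth TSVs
    and a JSON config echo. Returns the emitted paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seq, genes = build_genome(cfg)
    reads, truth = simulate_reads(cfg, seq, genes)

    fasta = out / "ref.fa"
    with open(fasta, "w") as fh:
        fh.write(f">{cfg.chrom}\n")
        for i in range(0, len(seq), 70):
            fh.write(seq[i : i + 70] + "\n")

    gtf = out / "genes.gtf"
    with open(gtf, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}"; gene_name "{g.gene_name}";'
            fh.write(
                "\t".join(
                    [cfg.chrom, "sim", "gene", str(g.span[0] + 1), str(g.span[1]), ".", g.strand, ".", attrs]
                )
                + "\n"
            )
            tattrs = attrs + f' transcript_id "{g.gene_id}.t1";'
            fh.write(
                "\t".join(
                    [cfg.chrom, "sim", "transcript", str(g.span[0] + 1), str(g.span[1]), ".", g.strand, ".", tattrs]
                )
                + "\n"
            )
            for es, ee in g.exons:
                fh.write(
                    "\t".join([cfg.chrom, "sim", "exon", str(es + 1), str(ee), ".", g.strand, ".", tattrs]) + "\n"
                )

    sam = out / "reads.sam"
    with open(sam, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        fh.write(f"@SQ\tSN:{cfg.chrom}\tLN:{len(seq)}\n")
        for _, line in _sam_records(cfg, genes, reads):
            fh.write(line + "\n")

    import pandas as pd

    pd.DataFrame(truth.genes).to_csv(out / "truth_genes.tsv", sep="\t", index=False)
    pd.DataFrame(truth.snps).to_csv(out / "truth_snps.tsv", sep="\t", index=False)
    pd.DataFrame(truth.reads).to_csv(out / "truth_reads.tsv", sep="\t", index=False)
    with open(out / "sim_config.json", "w") as fh:
        json.dump(dataclasses.asdict(cfg), fh, indent=1, sort_keys=True)
    return {
        "fasta": fasta,
        "gtf": gtf,
        "sam": sam,
        "truth_genes": out / "truth_genes.tsv",
        "truth_snps": out / "truth_snps.tsv",
        "truth_reads": out / "truth_reads.tsv",
    }
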