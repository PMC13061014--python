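"""Gene models from GTF and read-to-gene assignment.

Coordinates are 0-based half-open internally; GTF's 1-based closed intervals
are converted on load. Assignment supports a strict default mode (read fully
exonic in exactly one sense-strand gene) and a compat mode mirroring the
lenient behaviors of the GEDI/GrandSLAM toolchain: intronic classification of
unspliced reads, >=50% exon-overlap acceptance with splice-junction
concordance, and 1/(nTr * geneCount) read weighting. Each compat behavior is
an independent tri-state toggle (inherit/on/off).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from intervaltree import IntervalTree

Interval = tuple[int, int]


class GtfParseError(ValueError):
    pass


def merge_intervals(intervals: list[Interval]) -> list[Interval]:
    if not intervals:
        return []
    out: list[Interval] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


@dataclass
class GeneModel:
    gene_id: str
    gene_name: str
    chrom: str
    strand: str
    transcripts: dict[str, list[Interval]] = field(default_factory=dict)
    union_exons: list[Interval] = field(default_factory=list)

    @property
    def span(self) -> Interval:
        return (self.union_exons[0][0], self.union_exons[-1][1])

    def introns(self) -> list[Interval]:
        """Gaps between consecutive exons, per transcript, merged."""
        gaps: list[Interval] = []
        for exons in self.transcripts.values():
            for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
                _ = s1, e2
                gaps.append((e1, s2))
        return merge_intervals(gaps)

    def junctions(self) -> set[Interval]:
        out: set[Interval] = set()
        for exons in self.transcripts.values():
            for (_, e1), (s2, _) in zip(exons, exons[1:]):
                out.add((e1, s2))
        return out

    def finalize(self) -> None:
        for tid in self.transcripts:
            exons = sorted(self.transcripts[tid])
            for (s1, e1), (s2, _) in zip(exons, exons[1:]):
                _ = s1
                if s2 < e1:
                    raise GtfParseError(
                        f"overlapping exons in transcript {tid} of {self.gene_id}"
                    )
            self.transcripts[tid] = exons
        self.union_exons = merge_intervals(
            [iv for exons in self.transcripts.values() for iv in exons]
        )


def _parse_attributes(attr_field: str) -> dict[str, str]:
    attrs = {}
    for chunk in attr_field.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if " " not in chunk:
            continue
        key, _, value = chunk.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def load_annotation(gtf_path: str | Path) -> dict[str, GeneModel]:
    """Parse exon features from an ensembl/gencode-dialect GTF into GeneModels.

    Raises :class:`GtfParseError` naming the offending line for missing
    gene_id/transcript_id attributes or inverted coordinates.
    """
    genes: dict[str, GeneModel] = {}
    with open(gtf_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise GtfParseError(f"line {lineno}: expected 9 tab-separated fields")
            chrom, _, feature, start, end, _, strand, _, attr_field = fields[:9]
            if feature != "exon":
                continue
            start0, end0 = int(start) - 1, int(end)
            if start0 >= end0:
                raise GtfParseError(f"line {lineno}: exon start >= end")
            attrs = _parse_attributes(attr_field)
            if "gene_id" not in attrs:
                raise GtfParseError(f"line {lineno}: exon feature missing gene_id")
            if "transcript_id" not in attrs:
                raise GtfParseError(f"line {lineno}: exon feature missing transcript_id")
            gid = attrs["gene_id"]
            gene = genes.get(gid)
            if gene is None:
                gene = genes[gid] = GeneModel(
                    gene_id=gid,
                    gene_name=attrs.get("gene_name", gid),
                    chrom=chrom,
                    strand=strand,
                )
            gene.transcripts.setdefault(attrs["transcript_id"], []).append((start0, end0))
    for gene in genes.values():
        gene.finalize()
    return genes


class GeneIndex:
    """Interval lookup of gene spans per chromosome."""

    def __init__(self, genes: dict[str, GeneModel]):
        self.genes = genes
        self._trees: dict[str, IntervalTree] = {}
        for gene in genes.values():
            tree = self._trees.setdefault(gene.chrom, IntervalTree())
            s, e = gene.span
            tree.addi(s, e, gene.gene_id)

    def overlapping(self, chrom: str, start: int, end: int) -> list[GeneModel]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return sorted(
            (self.genes[iv.data] for iv in tree.overlap(start, end)),
            key=lambda g: g.gene_id,
        )


@dataclass
class ReadGeneAssignment:
    read_id: str
    gene_id: str
    category: str  # exonic | intronic | ambiguous | unassigned
    weight: float


@dataclass
class CompatOptions:
    """Tri-state compat behavior toggles; ``None`` inherits from the mode.

    ``resolve("gedi")`` flips all behaviors on unless individually overridden.
    """

    intronic: bool | None = None
    lenient: bool | None = None
    weighting: bool | None = None
    posfilter: bool | None = None

    def resolve(self, mode: str) -> "ResolvedCompat":
        base = mode == "gedi"
        return ResolvedCompat(
            intronic=base if self.intronic is None else self.intronic,
            lenient=base if self.lenient is None else self.lenient,
            weighting=base if self.weighting is None else self.weighting,
            posfilter=base if self.posfilter is None else self.posfilter,
        )


@dataclass
class ResolvedCompat:
    intronic: bool = False
    lenient: bool = False
    weighting: bool = False
    posfilter: bool = False


def _covered(intervals: list[Interval], start: int, end: int) -> int:
    """Bases of [start, end) covered by the interval list."""
    total = 0
    for s, e in intervals:
        total += max(0, min(e, end) - max(s, start))
    return total


def _blocks_within(blocks: list[Interval], intervals: list[Interval]) -> bool:
    for bs, be in blocks:
        if _covered(intervals, bs, be) != be - bs:
            return False
    return True


def _read_junctions(blocks: list[Interval]) -> list[Interval]:
    return [(e1, s2) for (_, e1), (s2, _) in zip(blocks, blocks[1:])]


def assign_read(
    read,
    index: GeneIndex,
    compat: ResolvedCompat | None = None,
    strandedness: str = "sense",
) -> list[ReadGeneAssignment]:
    """Assign one alignment to genes.

    Default mode: accepted iff every aligned block lies within the exon union
    of exactly one gene whose strand matches the read's transcription strand;
    multi-gene hits are ``ambiguous`` and excluded from counting. Compat mode
    adds intronic acceptance, the lenient >=50%-exon-overlap rule with
    junction concordance, and fractional 1/(nTr * geneCount) weights.
    """
    compat = compat or ResolvedCompat()
    blocks = [(s, e) for (s, e), _ in read.blocks]
    span = (blocks[0][0], blocks[-1][1])
    read_strand = read.alignment_strand
    if strandedness == "antisense":
        read_strand = "-" if read_strand == "+" else "+"
    aligned_len = sum(e - s for s, e in blocks)

    accepted: list[tuple[str, str]] = []  # (gene_id, category)
    for gene in index.overlapping(read.chrom, span[0], span[1]):
        if gene.strand != read_strand:
            continue
        if _blocks_within(blocks, gene.union_exons):
            accepted.append((gene.gene_id, "exonic"))
            continue
        if compat.lenient:
            overlap = sum(_covered(gene.union_exons, bs, be) for bs, be in blocks)
            junctions = _read_junctions(blocks)
            if overlap * 2 >= aligned_len and all(j in gene.junctions() for j in junctions):
                accepted.append((gene.gene_id, "exonic"))
                continue
        if compat.intronic and not read.is_spliced and _blocks_within(blocks, gene.introns()):
            accepted.append((gene.gene_id, "intronic"))

    if not accepted:
        return [ReadGeneAssignment(read.read_id, "", "unassigned", 0.0)]
    gene_count = len(accepted)
    if gene_count > 1 and not compat.weighting:
        return [
            ReadGeneAssignment(read.read_id, gid, "ambiguous", 0.0) for gid, _ in accepted
        ]
    n_alignments = max(1, read.n_alignments)
    weight = 1.0 if not compat.weighting else 1.0 / (n_alignments * gene_count)
    return [ReadGeneAssignment(read.read_id, gid, cat, weight) for gid, cat in accepted]
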