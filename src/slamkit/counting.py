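"""T>C conversion counting per read, per genomic site, and per read position.

All counting is on the gene's sense strand: for minus-strand genes a
reference A with read G (alignment-strand view) is the conversion event.
Masked genomic positions, trimmed read positions, bases below the quality
floor and Ns contribute to neither the numerator k nor the denominator n_T,
and are excluded from the site table as well so that SNP detection and NTR
estimation see the same position universe.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


@dataclass
class ReadConversionCount:
    read_id: str
    gene_id: str
    n_T: int
    k: int
    weight: float = 1.0
    category: str = "exonic"


class SiteTable:
    """Per-position sense-strand T pileup: coverage plus read-base counts.

    Keys are (chrom, position); values count the sense-strand read base
    observed over the site (index 0..3 for A/C/G/T). tc_count is the C count,
    the control class used for background estimation is the G count.
    """

    _BASE = {"A": 0, "C": 1, "G": 2, "T": 3}

    def __init__(self) -> None:
        self.sites: dict[tuple[str, int], list[int]] = {}

    def add(self, chrom: str, pos: int, sense_base: str) -> None:
        rec = self.sites.get((chrom, pos))
        if rec is None:
            rec = self.sites[(chrom, pos)] = [0, 0, 0, 0]
        rec[self._BASE[sense_base]] += 1

    def coverage(self, chrom: str, pos: int) -> int:
        return sum(self.sites.get((chrom, pos), (0, 0, 0, 0)))

    def tc_count(self, chrom: str, pos: int) -> int:
        return self.sites.get((chrom, pos), (0, 0, 0, 0))[1]

    def totals(self) -> dict[str, int]:
        cov = tc = tg = ta = 0
        for a, c, g, t in self.sites.values():
            cov += a + c + g + t
            tc += c
            tg += g
            ta += a
        return {"coverage": cov, "tc": tc, "tg": tg, "ta": ta}

    def fractions(self, min_cov: int) -> np.ndarray:
        """Mismatch fractions tc/coverage at sites with coverage >= min_cov."""
        out = []
        for a, c, g, t in self.sites.values():
            cov = a + c + g + t
            if cov >= min_cov:
                out.append(c / cov)
        return np.asarray(out, dtype=float)


class ConversionProfile:
    """Chunked per-read-position T coverage and conversion counts.

    Reads are partitioned round-robin into ``n_chunks`` by input order; the
    chunk dimension feeds the variance-based auto-trim estimator. Sums over
    chunks equal the unchunked totals exactly.
    """

    def __init__(self, n_chunks: int = 10, length: int = 0) -> None:
        self.n_chunks = n_chunks
        self.t_cov = np.zeros((n_chunks, length), dtype=np.int64)
        self.tc = np.zeros((n_chunks, length), dtype=np.int64)

    @property
    def length(self) -> int:
        return self.t_cov.shape[1]

    def _ensure(self, length: int) -> None:
        if length > self.length:
            pad = length - self.length
            self.t_cov = np.pad(self.t_cov, ((0, 0), (0, pad)))
            self.tc = np.pad(self.tc, ((0, 0), (0, pad)))

    def add(self, chunk: int, pos: int, converted: bool) -> None:
        self._ensure(pos + 1)
        c = chunk % self.n_chunks
        self.t_cov[c, pos] += 1
        if converted:
            self.tc[c, pos] += 1

    def total_t_cov(self) -> np.ndarray:
        return self.t_cov.sum(axis=0)

    def total_tc(self) -> np.ndarray:
        return self.tc.sum(axis=0)

    def rates(self) -> np.ndarray:
        cov = self.total_t_cov().astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(cov > 0, self.total_tc() / cov, np.nan)


def count_read(
    read,
    gene_strand: str,
    ref_seq: str,
    mask=None,
    trim5: int = 0,
    trim3: int = 0,
    q_floor: int = 20,
    *,
    site_table: SiteTable | None = None,
    profile: ConversionProfile | None = None,
    chunk: int = 0,
    allowed_qpos: set[int] | None = None,
) -> tuple[int, int]:
    """Count usable sense-strand T positions (n_T) and conversions (k).

    ``allowed_qpos`` restricts counting to a subset of query offsets; the
    paired-end overlap resolver uses it to count doubly-covered reference
    positions exactly once.
    """
    n_t = k = 0
    L = read.read_length
    reverse = read.alignment_strand == "-"
    want_ref = "T" if gene_strand == "+" else "A"
    seq = read.sequence
    quals = read.base_qualities
    for qpos, rpos in read.aligned_pairs():
        if rpos >= len(ref_seq):
            raise ValueError("reference window shorter than read blocks")
        if ref_seq[rpos] != want_ref:
            continue
        if allowed_qpos is not None and qpos not in allowed_qpos:
            continue
        if mask is not None and (read.chrom, rpos) in mask:
            continue
        seq_pos = L - 1 - qpos if reverse else qpos
        if seq_pos < trim5 or seq_pos >= L - trim3:
            continue
        if quals[qpos] < q_floor:
            continue
        base = seq[qpos]
        if base == "N":
            continue
        sense_base = base if gene_strand == "+" else _COMP[base]
        n_t += 1
        converted = sense_base == "C"
        if converted:
            k += 1
        if site_table is not None:
            site_table.add(read.chrom, rpos, sense_base)
        if profile is not None:
            profile.add(chunk, seq_pos, converted)
    return n_t, k


def resolve_pair_overlap(
    mate1, mate2, policy: str = "count_once"
) -> tuple[set[int], set[int]]:
    """Allowed query offsets per mate so overlap positions count once.

    ``count_once``: the mate with the higher base quality keeps a
    doubly-covered position (ties go to mate 1). ``drop_discordant``: a
    doubly-covered position where the mates disagree is excluded from both.
    """
    map1 = {rpos: qpos for qpos, rpos in mate1.aligned_pairs()}
    map2 = {rpos: qpos for qpos, rpos in mate2.aligned_pairs()}
    allowed1 = set(map1.values())
    allowed2 = set(map2.values())
    # SAM stores both mates on the reference strand, so bases at a shared
    # reference position are directly comparable regardless of orientation.
    for rpos in map1.keys() & map2.keys():
        q1, q2 = map1[rpos], map2[rpos]
        concordant = mate1.sequence[q1] == mate2.sequence[q2]
        if policy == "drop_discordant" and not concordant:
            allowed1.discard(q1)
            allowed2.discard(q2)
        elif mate2.base_qualities[q2] > mate1.base_qualities[q1]:
            allowed1.discard(q1)
        else:
            allowed2.discard(q2)
    return allowed1, allowed2


@dataclass
class GeneReadCounts:
    gene_id: str
    counts: list[tuple[int, int, float]] = field(default_factory=list)  # (n_i, k_i, w_i)

    @property
    def K(self) -> float:
        return sum(w * k for _, k, w in self.counts)

    @property
    def N_T(self) -> float:
        return sum(w * n for n, _, w in self.counts)

    @property
    def read_count(self) -> float:
        return sum(w for _, _, w in self.counts)


def aggregate_gene_counts(
    reads: list[ReadConversionCount], min_reads: int = 20
) -> tuple[dict[str, GeneReadCounts], set[str]]:
    """Group per-read counts by gene; returns (per-gene counts, low-coverage
    gene ids whose weighted read count is below ``min_reads``)."""
    per_gene: dict[str, GeneReadCounts] = {}
    for rc in reads:
        g = per_gene.setdefault(rc.gene_id, GeneReadCounts(rc.gene_id))
        g.counts.append((rc.n_T, rc.k, rc.weight))
    low = {gid for gid, g in per_gene.items() if g.read_count < min_reads}
    return per_gene, low
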