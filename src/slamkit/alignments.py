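"""Alignment ingest: SAM/BAM records into a uniform internal model.

Only matched (M/=/X) bases enter the model: soft-clipped bases are dropped and
indel bases are excluded from T accounting, since conversions are defined only
at aligned reference positions. Sortedness is checked on the fly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import pysam


class AlignmentInputError(ValueError):
    pass


@dataclass
class AlignedReadRecord:
    read_id: str
    chrom: str
    alignment_strand: str  # "+" | "-"
    blocks: list[tuple[tuple[int, int], int]]  # ((ref_start, ref_end), query_offset)
    sequence: str
    base_qualities: list[int]
    is_paired: bool = False
    is_first_mate: bool = True
    n_alignments: int = 1
    is_secondary: bool = False

    @property
    def is_spliced(self) -> bool:
        return len(self.blocks) > 1

    @property
    def read_length(self) -> int:
        return len(self.sequence)

    def aligned_pairs(self) -> Iterator[tuple[int, int]]:
        """Yield (query_offset, reference_position) for matched bases."""
        for (rs, re_), q0 in self.blocks:
            for i in range(re_ - rs):
                yield q0 + i, rs + i


def _blocks_from_cigar(aln: pysam.AlignedSegment) -> list[tuple[tuple[int, int], int]]:
    """Maximal co-linear matched runs; insertions/deletions split blocks."""
    blocks: list[tuple[tuple[int, int], int]] = []
    rpos = aln.reference_start
    qpos = 0
    for op, length in aln.cigartuples or []:
        if op in (0, 7, 8):  # M, =, X
            blocks.append(((rpos, rpos + length), qpos))
            rpos += length
            qpos += length
        elif op in (1, 4):  # I, S consume query
            qpos += length
        elif op in (2, 3):  # D, N consume reference
            rpos += length
        # H, P consume neither
    return blocks


def load_alignments(
    bam_path: str | Path,
    reference: pysam.FastaFile | None = None,
    include_secondary: bool = True,
) -> Iterator[AlignedReadRecord]:
    """Stream mapped alignments as :class:`AlignedReadRecord`.

    Unmapped records are skipped. ``n_alignments`` is taken from the NH tag
    (1 when absent). Raises :class:`AlignmentInputError` for a chromosome
    absent from the reference or for coordinate-unsorted input.
    """
    ref_names = set(reference.references) if reference is not None else None
    mode = "rb" if str(bam_path).endswith(".bam") else "r"
    last: tuple[str, int] | None = None
    seen_chroms: set[str] = set()
    with pysam.AlignmentFile(str(bam_path), mode, check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped:
                continue
            if aln.is_secondary and not include_secondary:
                continue
            chrom = aln.reference_name
            if ref_names is not None and chrom not in ref_names:
                raise AlignmentInputError(
                    f"alignment chromosome {chrom!r} absent from reference FASTA"
                )
            if last is not None:
                if chrom == last[0] and aln.reference_start < last[1]:
                    raise AlignmentInputError(
                        f"input not coordinate-sorted at {chrom}:{aln.reference_start + 1}"
                    )
                if chrom != last[0] and chrom in seen_chroms:
                    raise AlignmentInputError(
                        f"input not coordinate-sorted: chromosome {chrom} seen twice"
                    )
            if last is None or chrom != last[0]:
                seen_chroms.add(chrom)
            last = (chrom, aln.reference_start)
            blocks = _blocks_from_cigar(aln)
            if not blocks:
                continue
            quals = (
                list(aln.query_qualities)
                if aln.query_qualities is not None
                else [60] * len(aln.query_sequence or "")
            )
            yield AlignedReadRecord(
                read_id=aln.query_name,
                chrom=chrom,
                alignment_strand="-" if aln.is_reverse else "+",
                blocks=blocks,
                sequence=aln.query_sequence or "",
                base_qualities=quals,
                is_paired=aln.is_paired,
                is_first_mate=not aln.is_read2,
                n_alignments=int(aln.get_tag("NH")) if aln.has_tag("NH") else 1,
                is_secondary=aln.is_secondary,
            )


def load_reference(fasta_path: str | Path) -> pysam.FastaFile:
    """Open (and index if needed) a reference FASTA."""
    return pysam.FastaFile(str(fasta_path))
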