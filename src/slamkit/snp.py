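"""SNP masking: external BED/VCF masks and internal knee-detection.

A genomic T>C SNP produces a high mismatch fraction at its site in every
sample and would otherwise be read as labeling signal. The internal detector
histograms per-site mismatch fractions (sense-strand T sites with coverage
>= 10), log1p-normalizes the counts and finds the knee of the decreasing
curve as the bin of maximum distance below the descending diagonal
(Kneedle orientation for a decreasing curve). Guardrails: at least 1,000
eligible sites and knee strength > 0.02, otherwise the threshold falls back
to 0.22; a detected knee is clamped into [0.10, 0.60].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

FALLBACK_THRESHOLD = 0.22
CLAMP_LO, CLAMP_HI = 0.10, 0.60


class MaskParseError(ValueError):
    pass


class SnpMask:
    """Exact set of masked genomic positions, 0-based."""

    def __init__(self, positions: set[tuple[str, int]] | None = None) -> None:
        self.positions: set[tuple[str, int]] = set(positions or ())

    def __contains__(self, key: tuple[str, int]) -> bool:
        return key in self.positions

    def __len__(self) -> int:
        return len(self.positions)

    def __or__(self, other: "SnpMask") -> "SnpMask":
        return SnpMask(self.positions | other.positions)

    def add(self, chrom: str, pos: int) -> None:
        self.positions.add((chrom, pos))


def load_mask(path: str | Path, fmt: str | None = None) -> SnpMask:
    """Load a SNP mask from BED (0-based half-open, expanded per position)
    or VCF (SNV rows only; POS-1; indel records skipped with a warning)."""
    path = Path(path)
    if fmt is None:
        fmt = "VCF" if path.suffix.lower() in {".vcf", ".bcf"} or str(path).endswith(".vcf.gz") else "BED"
    fmt = fmt.upper()
    if fmt == "BED":
        return _load_bed(path)
    if fmt == "VCF":
        return _load_vcf(path)
    raise ValueError(f"unknown mask format {fmt!r}")


def _load_bed(path: Path) -> SnpMask:
    mask = SnpMask()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise MaskParseError(f"{path}:{lineno}: BED row needs >= 3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise MaskParseError(f"{path}:{lineno}: non-integer BED coordinates") from exc
            if start >= end:
                raise MaskParseError(f"{path}:{lineno}: BED start >= end")
            for pos in range(start, end):
                mask.add(fields[0], pos)
    return mask


def _load_vcf(path: Path) -> SnpMask:
    import pysam

    mask = SnpMask()
    skipped = 0
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            alts = rec.alts or ()
            if len(rec.ref or "") != 1 or any(len(a) != 1 for a in alts):
                skipped += 1
                continue
            mask.add(rec.chrom, rec.pos - 1)
    if skipped:
        warnings.warn(f"{path}: skipped {skipped} non-SNV VCF records", stacklevel=2)
    return mask


@dataclass
class KneeResult:
    threshold: float
    raw_knee: float
    strength: float
    eligible_sites: int
    clamped: bool = False
    fallback_used: bool = False
    histogram: list[int] = field(default_factory=list)
    bins: int = 100


def detect_threshold(site_table, min_cov: int = 10, bins: int = 100) -> KneeResult:
    """Knee-detect a mismatch-fraction threshold from the site table.

    The normalized histogram y (log1p counts, min-max scaled) decreases from
    its mass near zero; the knee bin maximizes d = (1 - x) - y, the distance
    below the diagonal from (0,1) to (1,0). The threshold is the lower edge
    of the knee bin, clamped to [0.10, 0.60]; guardrail failures (too few
    eligible sites, weak knee, or a degenerate flat histogram) fall back to
    the GEDI-parity value 0.22.
    """
    fractions = site_table.fractions(min_cov)
    eligible = len(fractions)
    counts, _ = np.histogram(fractions, bins=bins, range=(0.0, 1.0))
    hist = counts.tolist()
    y = np.log1p(counts.astype(float))
    if eligible == 0 or y.max() == y.min():
        return KneeResult(FALLBACK_THRESHOLD, 0.0, 0.0, eligible,
                          fallback_used=True, histogram=hist, bins=bins)
    y = (y - y.min()) / (y.max() - y.min())
    x = np.arange(bins, dtype=float) / (bins - 1)
    d = (1.0 - x) - y
    b_star = int(np.argmax(d))
    strength = float(d[b_star])
    raw_knee = b_star / bins
    if eligible < 1000 or strength <= 0.02:
        return KneeResult(FALLBACK_THRESHOLD, raw_knee, strength, eligible,
                          fallback_used=True, histogram=hist, bins=bins)
    threshold = min(max(raw_knee, CLAMP_LO), CLAMP_HI)
    return KneeResult(threshold, raw_knee, strength, eligible,
                      clamped=threshold != raw_knee, histogram=hist, bins=bins)


def build_mask(site_table, threshold: float, min_cov: int = 10) -> SnpMask:
    """Mask every eligible site whose mismatch fraction reaches the threshold."""
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    mask = SnpMask()
    for (chrom, pos), (a, c, g, t) in site_table.sites.items():
        cov = a + c + g + t
        if cov >= min_cov and c / cov >= threshold:
            mask.add(chrom, pos)
    return mask
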