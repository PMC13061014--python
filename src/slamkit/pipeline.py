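"""End-to-end offline SLAM-seq requantification.

Two-pass architecture over existing alignments: pass 1 assigns reads to
genes and builds the unmasked, untrimmed site table and chunked per-position
conversion profile; the SNP threshold/mask and the auto-trim window are then
derived; pass 2 recounts under the final mask and trim, estimates global
conversion rates and per-gene NTRs, and writes the output table, a run
manifest and the QC report. Re-running from an emitted manifest reproduces
the outputs byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pysam

from . import __version__
from .alignments import AlignedReadRecord, load_alignments, load_reference
from .annotation import CompatOptions, GeneIndex, ReadGeneAssignment, assign_read, load_annotation
from .autotrim import TrimSpec, auto_trim, compute_variance_curve, fit_piecewise
from .counting import (
    ConversionProfile,
    ReadConversionCount,
    SiteTable,
    aggregate_gene_counts,
    count_read,
    resolve_pair_overlap,
)
from .ntr import GlobalRates, estimate_gene_ntr, estimate_global_rates, write_output_table
from .qc import QcReport, write_qc
from .snp import KneeResult, SnpMask, build_mask, detect_threshold, load_mask

log = logging.getLogger("slamkit")

_TRISTATE = {"inherit": None, "on": True, "off": False}


@dataclass
class PipelineOptions:
    bam: list[str]
    fasta: str
    gtf: str
    out_prefix: str
    strandedness: str = "sense"
    compat: str = "none"  # none | gedi
    compat_intronic: str = "inherit"
    compat_lenient: str = "inherit"
    compat_weighting: str = "inherit"
    compat_posfilter: str = "inherit"
    snp_bed: str | None = None
    snp_vcf: str | None = None
    snp_detect: bool = False
    snp_min_cov: int = 10
    snp_bins: int = 100
    snp_threshold: float | None = None
    auto_trim: str = "none"  # none | variance
    trim_scope: str = "first"  # first | per-file
    trim5: int | None = None
    trim3: int | None = None
    trim_chunks: int = 10
    trim_window: int = 5
    elevation_factor: float = 1.5
    min_base_qual: int = 20
    p_old: float | None = None
    p_new: float | None = None
    control_class: str = "tg"
    rate_method: str = "em"  # em (both rates free) | control (p_old pinned)
    min_reads: int = 20
    output_schema: str = "native"
    posterior: str = "profile"
    qc_report: bool = True
    html: bool = False
    seed: int = 0

    def resolved_compat(self):
        return CompatOptions(
            intronic=_TRISTATE[self.compat_intronic],
            lenient=_TRISTATE[self.compat_lenient],
            weighting=_TRISTATE[self.compat_weighting],
            posfilter=_TRISTATE[self.compat_posfilter],
        ).resolve(self.compat)


@dataclass
class RunResult:
    table_path: Path
    manifest_path: Path
    estimates: list
    rates: GlobalRates
    knee: KneeResult | None
    trims: dict[str, TrimSpec]
    mask: SnpMask
    site_table: SiteTable
    site_table_pass1: SiteTable
    profiles_pass1: dict[str, ConversionProfile]
    read_counts: list[ReadConversionCount]
    qc: QcReport | None
    category_counts: dict[str, float]


class _Fragment:
    """One countable unit: a single-end read or a mate pair."""

    __slots__ = ("records", "gene_id", "category", "weight")

    def __init__(self, records, gene_id, category, weight):
        self.records = records
        self.gene_id = gene_id
        self.category = category
        self.weight = weight


def _collect_fragments(
    bam_path: str,
    reference: pysam.FastaFile,
    index: GeneIndex,
    compat,
    strandedness: str,
) -> tuple[list[_Fragment], dict[str, float]]:
    """Load, assign and pair alignments of one file."""
    include_secondary = compat.weighting
    singles: list[tuple[AlignedReadRecord, ReadGeneAssignment]] = []
    pending: dict[tuple[str, str], tuple[AlignedReadRecord, ReadGeneAssignment]] = {}
    stats = {"seen": 0, "assigned": 0.0, "ambiguous": 0, "unassigned": 0, "intronic": 0.0}
    for rec in load_alignments(bam_path, reference, include_secondary=include_secondary):
        stats["seen"] += 1
        for asg in assign_read(rec, index, compat, strandedness):
            if asg.category == "unassigned":
                stats["unassigned"] += 1
                continue
            if asg.category == "ambiguous":
                stats["ambiguous"] += 1
                continue
            stats["assigned"] += asg.weight
            if asg.category == "intronic":
                stats["intronic"] += asg.weight
            if rec.is_paired:
                key = (rec.read_id, asg.gene_id)
                if key in pending:
                    mate, masg = pending.pop(key)
                    singles.append(
                        (_Fragment([mate, rec], asg.gene_id, masg.category, masg.weight), None)
                    )
                else:
                    pending[key] = (rec, asg)
            else:
                singles.append((_Fragment([rec], asg.gene_id, asg.category, asg.weight), None))
    # unpaired leftovers (mate unmapped or assigned elsewhere) count alone
    for rec, asg in pending.values():
        singles.append((_Fragment([rec], asg.gene_id, asg.category, asg.weight), None))
    return [s[0] for s in singles], stats


def _count_pass(
    fragments: list[_Fragment],
    index: GeneIndex,
    ref_cache: dict[str, str],
    mask: SnpMask | None,
    trim: TrimSpec,
    q_floor: int,
    n_chunks: int,
    pe_policy: str,
    site_table: SiteTable,
    profile: ConversionProfile,
) -> list[ReadConversionCount]:
    out: list[ReadConversionCount] = []
    for serial, frag in enumerate(fragments):
        gene = index.genes[frag.gene_id]
        ref_seq = ref_cache[gene.chrom]
        chunk = serial % n_chunks
        if len(frag.records) == 2:
            a1, a2 = resolve_pair_overlap(frag.records[0], frag.records[1], pe_policy)
            allowed = [a1, a2]
        else:
            allowed = [None]
        n_t = k = 0
        for rec, allow in zip(frag.records, allowed):
            dn, dk = count_read(
                rec,
                gene.strand,
                ref_seq,
                mask=mask,
                trim5=trim.trim5,
                trim3=trim.trim3,
                q_floor=q_floor,
                site_table=site_table,
                profile=profile,
                chunk=chunk,
                allowed_qpos=allow,
            )
            n_t += dn
            k += dk
        out.append(
            ReadConversionCount(
                frag.records[0].read_id, frag.gene_id, n_t, k, frag.weight, frag.category
            )
        )
    return out


def run_quant(opts: PipelineOptions) -> RunResult:
    """Run the full quantification pipeline; see the module docstring."""
    out_prefix = Path(opts.out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)

    genes = load_annotation(opts.gtf)
    index = GeneIndex(genes)
    log.info("annotation: %d genes", len(genes))
    reference = load_reference(opts.fasta)
    ref_cache = {name: reference.fetch(name) for name in reference.references}
    compat = opts.resolved_compat()
    pe_policy = "drop_discordant" if compat.posfilter else "count_once"

    per_file_fragments: dict[str, list[_Fragment]] = {}
    site_pass1 = SiteTable()
    profiles_pass1: dict[str, ConversionProfile] = {}
    zero_trim = TrimSpec()
    for bam in opts.bam:
        frags, stats = _collect_fragments(bam, reference, index, compat, opts.strandedness)
        per_file_fragments[bam] = frags
        profile = ConversionProfile(opts.trim_chunks)
        _count_pass(
            frags, index, ref_cache, None, zero_trim, opts.min_base_qual,
            opts.trim_chunks, pe_policy, site_pass1, profile,
        )
        profiles_pass1[bam] = profile
        log.info(
            "pass1 %s: %d alignments seen, %.1f assigned, %d ambiguous, %d unassigned",
            bam, stats["seen"], stats["assigned"], stats["ambiguous"], stats["unassigned"],
        )

    # --- SNP mask -----------------------------------------------------------
    mask = SnpMask()
    mask_sources = []
    if opts.snp_bed:
        mask = mask | load_mask(opts.snp_bed, "BED")
        mask_sources.append("bed")
    if opts.snp_vcf:
        mask = mask | load_mask(opts.snp_vcf, "VCF")
        mask_sources.append("vcf")
    knee: KneeResult | None = None
    if opts.snp_detect:
        if opts.snp_threshold is not None:
            knee = KneeResult(
                threshold=opts.snp_threshold, raw_knee=opts.snp_threshold,
                strength=float("nan"), eligible_sites=len(site_pass1.fractions(opts.snp_min_cov)),
            )
        else:
            knee = detect_threshold(site_pass1, min_cov=opts.snp_min_cov, bins=opts.snp_bins)
        auto = build_mask(site_pass1, knee.threshold, min_cov=opts.snp_min_cov)
        mask = mask | auto
        mask_sources.append("auto")
        log.info(
            "snp: threshold %.3f (fallback=%s clamped=%s), %d sites masked",
            knee.threshold, knee.fallback_used, knee.clamped, len(mask),
        )

    # --- trim ---------------------------------------------------------------
    trims: dict[str, TrimSpec] = {}
    if opts.trim5 is not None or opts.trim3 is not None:
        manual = TrimSpec(trim5=opts.trim5 or 0, trim3=opts.trim3 or 0, scope="manual")
        trims = {bam: manual for bam in opts.bam}
    elif opts.auto_trim == "variance":
        if opts.trim_scope == "first":
            spec = auto_trim(
                profiles_pass1[opts.bam[0]], window=opts.trim_window,
                elevation_factor=opts.elevation_factor, scope="first",
            )
            trims = {bam: spec for bam in opts.bam}
        else:
            trims = {
                bam: auto_trim(
                    profiles_pass1[bam], window=opts.trim_window,
                    elevation_factor=opts.elevation_factor, scope="per-file",
                )
                for bam in opts.bam
            }
        for bam, spec in trims.items():
            log.info("trim %s: 5'=%d 3'=%d (%d segments)", bam, spec.trim5, spec.trim3, spec.n_segments)
    else:
        trims = {bam: zero_trim for bam in opts.bam}

    # --- pass 2 -------------------------------------------------------------
    site_pass2 = SiteTable()
    read_counts: list[ReadConversionCount] = []
    profile_pass2 = ConversionProfile(opts.trim_chunks)
    for bam in opts.bam:
        read_counts.extend(
            _count_pass(
                per_file_fragments[bam], index, ref_cache, mask, trims[bam],
                opts.min_base_qual, opts.trim_chunks, pe_policy, site_pass2, profile_pass2,
            )
        )
    log.info("pass2: %d fragments counted over %d files", len(read_counts), len(opts.bam))

    # --- model --------------------------------------------------------------
    all_counts = [(rc.n_T, rc.k, rc.weight) for rc in read_counts]
    per_gene, _low = aggregate_gene_counts(read_counts, opts.min_reads)
    rates = estimate_global_rates(
        all_counts, site_pass2, p_old=opts.p_old, p_new=opts.p_new,
        control_class=opts.control_class, rate_method=opts.rate_method,
        gene_groups={gid: per_gene[gid].counts for gid in sorted(per_gene)},
    )
    log.info("rates: p_old=%.3e p_new=%.3e (%s)", rates.p_old, rates.p_new, rates.source)
    estimates = []
    for gid in sorted(genes):
        counts = per_gene[gid].counts if gid in per_gene else []
        estimates.append(
            estimate_gene_ntr(
                gid, counts, rates, gene_name=genes[gid].gene_name,
                posterior=opts.posterior, min_reads=opts.min_reads,
            )
        )

    category_counts: dict[str, float] = {}
    for rc in read_counts:
        category_counts[rc.category] = category_counts.get(rc.category, 0.0) + rc.weight

    table_path = Path(f"{opts.out_prefix}.ntr.tsv")
    write_output_table(estimates, table_path, schema=opts.output_schema)

    manifest = build_manifest(opts, rates, knee, trims, mask_sources, category_counts)
    manifest_path = Path(f"{opts.out_prefix}.manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)

    qc = None
    if opts.qc_report:
        qc = QcReport.build(
            profiles_pass1=profiles_pass1,
            profile_pass2=profile_pass2,
            trims=trims,
            knee=knee,
            estimates=estimates,
            trim_window=opts.trim_window,
        )
        write_qc(qc, f"{opts.out_prefix}.qc", html=opts.html)

    return RunResult(
        table_path=table_path, manifest_path=manifest_path, estimates=estimates,
        rates=rates, knee=knee, trims=trims, mask=mask, site_table=site_pass2,
        site_table_pass1=site_pass1, profiles_pass1=profiles_pass1,
        read_counts=read_counts, qc=qc, category_counts=category_counts,
    )


def build_manifest(opts, rates, knee, trims, mask_sources, category_counts) -> dict:
    return {
        "version": __version__,
        "seed": opts.seed,
        "options": dataclasses.asdict(opts),
        "rates": dataclasses.asdict(rates),
        "knee": None if knee is None else {
            "threshold": knee.threshold, "raw_knee": knee.raw_knee,
            "strength": None if knee.strength != knee.strength else knee.strength,
            "eligible_sites": knee.eligible_sites,
            "clamped": knee.clamped, "fallback_used": knee.fallback_used,
        },
        "mask_sources": mask_sources,
        "trim": {
            bam: {"trim5": t.trim5, "trim3": t.trim3, "breakpoints": t.breakpoints,
                  "n_segments": t.n_segments, "scope": t.scope, "warning": t.warning}
            for bam, t in trims.items()
        },
        "category_counts": category_counts,
    }


def run_from_manifest(manifest_path: str | Path) -> RunResult:
    """Re-run the pipeline from an emitted manifest; outputs are reproduced
    byte-identically for identical inputs."""
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    opts = PipelineOptions(**manifest["options"])
    return run_quant(opts)
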