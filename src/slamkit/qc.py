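"""Self-contained QC report (JSON always, single-file HTML on request).

The JSON schema is the tested contract: keys ``per_position_rates``,
``variance_fit``, ``snp_histogram``, ``ntr_summary`` and ``guardrails`` are
always present, with all arrays inline. The HTML view embeds its plots as
inline SVG and references no external resources, so it opens offline.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np


def _clean(obj):
    """JSON-safe: numpy scalars to python, NaN to None."""
    if isinstance(obj, dict):
        return {k: _clean(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_clean(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if math.isnan(v) or math.isinf(v) else v
    if isinstance(obj, np.ndarray):
        return _clean(obj.tolist())
    return obj


@dataclass
class QcReport:
    payload: dict

    @classmethod
    def build(cls, profiles_pass1, profile_pass2, trims, knee, estimates, trim_window=5):
        from .autotrim import compute_variance_curve

        per_position = {}
        variance_fit = {}
        for name, profile in profiles_pass1.items():
            rates = profile.rates()
            per_position[name] = {
                "t_coverage": profile.total_t_cov().tolist(),
                "tc_count": profile.total_tc().tolist(),
                "rate": rates.tolist(),
            }
            trim = trims.get(name)
            entry = {
                "sd": None,
                "smoothed_sd": None,
                "breakpoints": [] if trim is None else list(trim.breakpoints),
                "n_segments": 0 if trim is None else trim.n_segments,
                "bic": {} if trim is None else {str(k): v for k, v in trim.bic.items()},
                "trim5": 0 if trim is None else trim.trim5,
                "trim3": 0 if trim is None else trim.trim3,
                "warning": "" if trim is None else trim.warning,
            }
            if profile.n_chunks >= 2 and profile.length > 0:
                curve = compute_variance_curve(profile, window=trim_window)
                entry["sd"] = curve.sd.tolist()
                entry["smoothed_sd"] = curve.smoothed_sd.tolist()
            variance_fit[name] = entry

        snp_histogram = None
        guardrails = {"snp_fallback_used": False, "snp_fallback_value": 0.22,
                      "snp_clamped": False, "trim_warnings": {}}
        if knee is not None:
            snp_histogram = {
                "bin_counts": list(knee.histogram),
                "bins": knee.bins,
                "threshold": knee.threshold,
                "raw_knee": knee.raw_knee,
                "strength": knee.strength,
                "eligible_sites": knee.eligible_sites,
            }
            guardrails.update(
                snp_fallback_used=knee.fallback_used,
                snp_clamped=knee.clamped,
                snp_threshold=knee.threshold,
                snp_eligible_sites=knee.eligible_sites,
            )
        for name, trim in trims.items():
            if trim.warning:
                guardrails["trim_warnings"][name] = trim.warning

        means = [e.ntr_mean for e in estimates if e.quantified]
        hist, edges = np.histogram(means, bins=20, range=(0.0, 1.0)) if means else (np.zeros(20, int), np.linspace(0, 1, 21))
        ntr_summary = {
            "n_genes": len(estimates),
            "n_quantified": sum(e.quantified for e in estimates),
            "ntr_mean": {e.gene_id: e.ntr_mean for e in estimates},
            "histogram": {"counts": hist.tolist(), "edges": edges.tolist()},
        }
        return cls(
            payload=_clean(
                {
                    "per_position_rates": per_position,
                    "variance_fit": variance_fit,
                    "snp_histogram": snp_histogram,
                    "ntr_summary": ntr_summary,
                    "guardrails": guardrails,
                }
            )
        )


def _svg_plot(plot_fn) -> str:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6.5, 3.2))
    plot_fn(ax)
    buf = io.StringIO()
    fig.tight_layout()
    fig.savefig(buf, format="svg")
    plt.close(fig)
    svg = buf.getvalue()
    return svg[svg.index("<svg") :]


def render_html(report: QcReport) -> str:
    p = report.payload
    sections = []
    for name, pp in p["per_position_rates"].items():
        rate = [r if r is not None else float("nan") for r in pp["rate"]]

        def plot_rates(ax, rate=rate, name=name):
            ax.plot(rate, lw=1.2)
            ax.set_xlabel("read position")
            ax.set_ylabel("T>C rate")
            ax.set_title(f"Per-position conversion rate: {name}")

        sections.append(_svg_plot(plot_rates))
        vf = p["variance_fit"].get(name) or {}
        if vf.get("smoothed_sd"):
            sm = [v if v is not None else float("nan") for v in vf["smoothed_sd"]]

            def plot_var(ax, sm=sm, vf=vf, name=name):
                ax.plot(sm, lw=1.2, label="smoothed SD")
                for b in vf["breakpoints"]:
                    ax.axvline(b, color="crimson", ls="--", lw=0.8)
                ax.set_xlabel("read position")
                ax.set_ylabel("SD of rate")
                ax.set_title(f"Auto-trim variance curve: {name} (trim {vf['trim5']}/{vf['trim3']})")
                ax.legend(frameon=False)

            sections.append(_svg_plot(plot_var))
    if p["snp_histogram"]:
        sh = p["snp_histogram"]

        def plot_snp(ax, sh=sh):
            edges = np.linspace(0, 1, sh["bins"] + 1)[:-1]
            ax.bar(edges, np.log1p(sh["bin_counts"]), width=1.0 / sh["bins"], align="edge")
            ax.axvline(sh["threshold"], color="crimson", ls="--", label=f"threshold {sh['threshold']:.2f}")
            ax.set_xlabel("mismatch fraction")
            ax.set_ylabel("log1p(site count)")
            ax.set_title("SNP detection histogram")
            ax.legend(frameon=False)

        sections.append(_svg_plot(plot_snp))
    ns = p["ntr_summary"]

    def plot_ntr(ax, ns=ns):
        edges = ns["histogram"]["edges"][:-1]
        ax.bar(edges, ns["histogram"]["counts"], width=0.05, align="edge")
        ax.set_xlabel("NTR (posterior mean)")
        ax.set_ylabel("genes")
        ax.set_title(f"Per-gene NTR ({ns['n_quantified']}/{ns['n_genes']} quantified)")

    sections.append(_svg_plot(plot_ntr))
    guard = json.dumps(p["guardrails"], indent=1, sort_keys=True)
    body = "\n".join(f"<div class='plot'>{s}</div>" for s in sections)
    return (
        "<!DOCTYPE html><html><head><meta charset='utf-8'><title>SLAM QC report</title>"
        "<style>body{font-family:sans-serif;max-width:860px;margin:2em auto}"
        ".plot{margin-bottom:1.5em}pre{background:#f5f5f5;padding:1em}</style></head><body>"
        "<h1>SLAM QC report</h1>"
        f"{body}<h2>Guardrails</h2><pre>{guard}</pre></body></html>"
    )


def write_qc(report: QcReport, out_prefix: str | Path, html: bool = False) -> dict[str, Path]:
    json_path = Path(f"{out_prefix}.json")
    with open(json_path, "w") as fh:
        json.dump(report.payload, fh, indent=1, sort_keys=True)
    paths = {"json": json_path}
    if html:
        html_path = Path(f"{out_prefix}.html")
        html_path.write_text(render_html(report))
        paths["html"] = html_path
    return paths
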