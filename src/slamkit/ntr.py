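"""Per-gene new-to-total RNA ratio (NTR) via a binomial mixture with EM.

Each assigned read contributes (n_i usable T positions, k_i conversions,
weight w_i). Reads are modeled as a two-component binomial mixture: newly
synthesized RNA converts T at rate p_new, pre-existing RNA at the background
rate p_old, and the mixing weight pi is the gene's NTR:

    L(pi) = prod_i [ pi B(k_i; n_i, p_new) + (1 - pi) B(k_i; n_i, p_old) ]^{w_i}

EM maximizes L; the reported uncertainty is a Beta distribution matched to
the exact posterior of pi under a uniform prior (moments computed on a grid
over the observed-data likelihood), from which MAP/mean and the 0.05/0.95
credible quantiles are taken. A simpler effective-count posterior
(Beta(1 + sum w*gamma, 1 + sum w*(1-gamma))) is available as
``posterior="counts"``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats


class NtrModelError(ValueError):
    pass


@dataclass
class GlobalRates:
    p_old: float
    p_new: float
    source: str = "estimated"  # estimated | user
    pi_pooled: float | None = None
    control_class: str = "tg"

    def validate(self) -> None:
        if not (0.0 <= self.p_old < self.p_new <= 1.0):
            raise NtrModelError("require 0 <= p_old < p_new <= 1")


@dataclass
class GeneNtrEstimate:
    gene_id: str
    gene_name: str
    read_count: float
    conversions: float  # weighted K
    t_coverage: float  # weighted N_T
    alpha: float
    beta: float
    ntr_map: float
    ntr_mean: float
    ntr_q05: float
    ntr_q95: float
    em_iterations: int
    converged: bool
    quantified: bool = True


def _collapse(counts: list[tuple[int, int, float]]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unique (n, k) classes with summed weights; n_i = 0 reads are dropped
    (they carry no likelihood information)."""
    agg: dict[tuple[int, int], float] = {}
    for n, k, w in counts:
        if n <= 0 or w <= 0:
            continue
        agg[(n, k)] = agg.get((n, k), 0.0) + w
    if not agg:
        return np.empty(0, int), np.empty(0, int), np.empty(0, float)
    nk = sorted(agg)
    n = np.array([t[0] for t in nk])
    k = np.array([t[1] for t in nk])
    w = np.array([agg[t] for t in nk])
    return n, k, w


def mixture_loglik(
    n: np.ndarray, k: np.ndarray, w: np.ndarray, pi, p_new: float, p_old: float
) -> np.ndarray:
    """Weighted observed-data log-likelihood, vectorized over pi."""
    a = stats.binom.pmf(k, n, p_new)
    b = stats.binom.pmf(k, n, p_old)
    pi_arr = np.atleast_1d(np.asarray(pi, dtype=float))[:, None]
    mix = pi_arr * a + (1.0 - pi_arr) * b
    with np.errstate(divide="ignore"):
        ll = (w * np.log(mix)).sum(axis=1)
    return ll if np.ndim(pi) else float(ll[0])


def _em(
    n: np.ndarray,
    k: np.ndarray,
    w: np.ndarray,
    p_new: float,
    p_old: float,
    pi0: float = 0.1,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> tuple[float, np.ndarray, int, bool, list[float]]:
    """EM for the mixing weight with fixed component rates.

    Returns (pi, responsibilities, iterations, converged, loglik trace).
    """
    a = stats.binom.pmf(k, n, p_new)
    b = stats.binom.pmf(k, n, p_old)
    pi = pi0
    gamma = np.full(len(n), pi)
    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        num = pi * a
        den = num + (1.0 - pi) * b
        gamma = np.where(den > 0, num / np.maximum(den, 1e-300), 0.5)
        new_pi = float((w * gamma).sum() / w.sum())
        with np.errstate(divide="ignore"):
            trace.append(float((w * np.log(np.maximum(den, 1e-300))).sum()))
        if abs(new_pi - pi) < tol:
            pi = new_pi
            converged = True
            break
        pi = new_pi
    return pi, gamma, it, converged, trace


def estimate_global_rates(
    all_counts: list[tuple[int, int, float]],
    site_table=None,
    p_old: float | None = None,
    p_new: float | None = None,
    control_class: str = "tg",
    rate_method: str = "em",
    gene_groups: dict[str, list[tuple[int, int, float]]] | None = None,
    tol: float = 1e-9,
    max_iter: int = 5000,
) -> GlobalRates:
    """Estimate the background and labeled conversion rates from the pool.

    A control substitution class at sense-strand T sites (default T>G;
    ``control_class="mean"`` averages the T>A and T>G class rates) anchors
    the sequencing-error floor -- error is class-symmetric while labeling is
    T>C-specific. With ``rate_method="em"`` (default) both rates are then
    fitted by EM on the two-component binomial mixture, the control rate
    serving as the p_old initializer; this also captures any T>C-specific
    background in unlabeled RNA that a control class cannot see. When
    ``gene_groups`` is supplied the EM fits one mixing weight per gene with
    shared rates: genes with little labeling pin down p_old and strongly
    labeled genes pin down p_new, which identifies the rates far more
    sharply than the single pooled mixing weight (whose profile likelihood
    in p_old is nearly flat). ``rate_method="control"`` pins p_old at the
    control-class rate and fits p_new only. User-supplied values
    short-circuit estimation.
    """
    p_old_given = p_old is not None
    if p_old_given and p_new is not None:
        rates = GlobalRates(p_old=p_old, p_new=p_new, source="user")
        rates.validate()
        return rates

    control_rate = None
    if p_old is None:
        if site_table is None:
            raise NtrModelError("p_old estimation requires a site table (or supply --p-old)")
        tot = site_table.totals()
        if tot["coverage"] == 0:
            raise NtrModelError("empty site table; cannot estimate background rate")
        if control_class == "tg":
            control_rate = tot["tg"] / tot["coverage"]
        elif control_class == "mean":
            control_rate = 0.5 * (tot["tg"] + tot["ta"]) / tot["coverage"]
        else:
            raise ValueError(f"unknown control class {control_class!r}")
        p_old = max(control_rate, 1e-6)

    n, k, w = _collapse(all_counts)
    if len(n) == 0 or k.sum() == 0:
        raise NtrModelError(
            "no conversion signal in pooled reads; supply --p-old/--p-new explicitly"
        )
    if p_new is not None:
        rates = GlobalRates(p_old=p_old, p_new=p_new, source="user" if p_old_given else "estimated")
        rates.validate()
        return rates

    free_p_old = rate_method == "em" and not p_old_given
    pooled_rate = float((w * k).sum() / (w * n).sum())
    p_new_hat = float(np.clip(2.0 * pooled_rate - p_old, max(5.0 * p_old, 1e-4), 0.95))
    p_old_hat = float(p_old)

    if gene_groups:
        # one mixing weight per gene, shared rates
        parts = [_collapse(c) for c in gene_groups.values()]
        parts = [(gn, gk, gw) for gn, gk, gw in parts if len(gn)]
        n = np.concatenate([p[0] for p in parts])
        k = np.concatenate([p[1] for p in parts])
        w = np.concatenate([p[2] for p in parts])
        group = np.concatenate(
            [np.full(len(p[0]), gi) for gi, p in enumerate(parts)]
        )
        n_groups = len(parts)
        wsum = np.bincount(group, weights=w, minlength=n_groups)
    else:
        group = np.zeros(len(n), dtype=int)
        n_groups = 1
        wsum = np.array([w.sum()])

    pis = np.full(n_groups, 0.5)
    for _ in range(max_iter):
        a = stats.binom.pmf(k, n, p_new_hat)
        b = stats.binom.pmf(k, n, p_old_hat)
        num = pis[group] * a
        den = num + (1.0 - pis[group]) * b
        gamma = np.where(den > 0, num / np.maximum(den, 1e-300), 0.5)
        new_pis = np.bincount(group, weights=w * gamma, minlength=n_groups) / wsum
        denom = (w * gamma * n).sum()
        new_p_new = float((w * gamma * k).sum() / denom) if denom > 0 else 0.0
        if free_p_old:
            denom0 = (w * (1.0 - gamma) * n).sum()
            new_p_old = float((w * (1.0 - gamma) * k).sum() / denom0) if denom0 > 0 else p_old_hat
        else:
            new_p_old = p_old_hat
        delta = max(
            float(np.abs(new_pis - pis).max()),
            abs(new_p_new - p_new_hat),
            abs(new_p_old - p_old_hat),
        )
        pis, p_new_hat, p_old_hat = new_pis, new_p_new, new_p_old
        if delta < tol:
            break
    pi = float((pis * wsum).sum() / wsum.sum())
    if p_new_hat < p_old_hat:  # label swap in the free-rate fit
        p_new_hat, p_old_hat, pi = p_old_hat, p_new_hat, 1.0 - pi
    if p_new_hat <= p_old_hat:
        raise NtrModelError(
            f"estimated p_new ({p_new_hat:.2e}) <= p_old ({p_old_hat:.2e}): no labeling "
            "signal detected; supply --p-old/--p-new explicitly"
        )
    return GlobalRates(
        p_old=p_old_hat, p_new=p_new_hat, pi_pooled=pi, control_class=control_class
    )


def _beta_map(alpha: float, beta: float) -> float:
    if alpha > 1.0 and beta > 1.0:
        return (alpha - 1.0) / (alpha + beta - 2.0)
    if alpha <= 1.0 and beta > 1.0:
        return 0.0
    if alpha > 1.0 and beta <= 1.0:
        return 1.0
    return alpha / (alpha + beta)


def _profile_posterior(
    n: np.ndarray, k: np.ndarray, w: np.ndarray, p_new: float, p_old: float, grid: int = 1001
) -> tuple[float, float]:
    """Moment-matched Beta(alpha, beta) to the exact posterior of pi on a
    uniform grid (uniform prior)."""
    pis = np.linspace(0.0, 1.0, grid)
    ll = mixture_loglik(n, k, w, pis, p_new, p_old)
    ll = ll - ll.max()
    post = np.exp(ll)
    z = np.trapezoid(post, pis)
    post /= z
    mean = float(np.trapezoid(post * pis, pis))
    var = float(np.trapezoid(post * (pis - mean) ** 2, pis))
    var = min(max(var, 1e-12), mean * (1.0 - mean) * 0.9999) if 0 < mean < 1 else max(var, 1e-12)
    nu = mean * (1.0 - mean) / var - 1.0
    alpha = max(mean * nu, 1e-6)
    beta = max((1.0 - mean) * nu, 1e-6)
    return alpha, beta


def estimate_gene_ntr(
    gene_id: str,
    counts: list[tuple[int, int, float]],
    rates: GlobalRates,
    gene_name: str = "",
    tol: float = 1e-8,
    max_iter: int = 1000,
    posterior: str = "profile",
    min_reads: int = 20,
) -> GeneNtrEstimate:
    """Fit the per-gene NTR and its Beta credible summary."""
    rates.validate()
    read_count = sum(w for _, _, w in counts)
    K = sum(w * k for _, k, w in counts)
    N_T = sum(w * n for n, _, w in counts)
    n, k, w = _collapse(counts)
    if len(n) == 0:
        return GeneNtrEstimate(
            gene_id, gene_name or gene_id, read_count, K, N_T,
            alpha=1.0, beta=1.0, ntr_map=0.5, ntr_mean=0.5,
            ntr_q05=0.05, ntr_q95=0.95, em_iterations=0, converged=False,
            quantified=read_count >= min_reads,
        )
    pi, gamma, iters, converged, _ = _em(
        n, k, w, rates.p_new, rates.p_old, tol=tol, max_iter=max_iter
    )
    if posterior == "counts":
        alpha = 1.0 + float((w * gamma).sum())
        beta = 1.0 + float((w * (1.0 - gamma)).sum())
    elif posterior == "profile":
        alpha, beta = _profile_posterior(n, k, w, rates.p_new, rates.p_old)
    else:
        raise ValueError(f"unknown posterior method {posterior!r}")
    q05, q95 = stats.beta.ppf([0.05, 0.95], alpha, beta)
    return GeneNtrEstimate(
        gene_id, gene_name or gene_id, read_count, K, N_T,
        alpha=float(alpha), beta=float(beta),
        ntr_map=float(_beta_map(alpha, beta)),
        ntr_mean=float(alpha / (alpha + beta)),
        ntr_q05=float(q05), ntr_q95=float(q95),
        em_iterations=iters, converged=converged,
        quantified=read_count >= min_reads,
    )


NATIVE_COLUMNS = [
    "gene_id", "gene_name", "read_count", "conversions", "t_coverage",
    "ntr_map", "ntr_mean", "ntr_q05", "ntr_q95", "alpha", "beta",
    "converged", "quantified",
]


def load_grandslam_schema(path: str | Path | None = None) -> list[tuple[str, str]]:
    """Header mapping for the GrandSLAM dialect; a user file overrides the
    packaged default so parity with any GrandSLAM version is adjustable."""
    if path is None:
        raw = resources.files("slamkit.data").joinpath("grandslam_schema.json").read_text()
    else:
        raw = Path(path).read_text()
    return [tuple(pair) for pair in json.loads(raw)["columns"]]


def estimates_to_frame(estimates: list[GeneNtrEstimate]) -> pd.DataFrame:
    rows = [{c: getattr(e, c) for c in NATIVE_COLUMNS} for e in estimates]
    return pd.DataFrame(rows, columns=NATIVE_COLUMNS)


def write_output_table(
    estimates: list[GeneNtrEstimate],
    path: str | Path,
    schema: str = "native",
    schema_path: str | Path | None = None,
) -> pd.DataFrame:
    """Write the per-gene table as TSV in the native or GrandSLAM dialect."""
    df = estimates_to_frame(sorted(estimates, key=lambda e: e.gene_id))
    if schema == "grandslam":
        mapping = load_grandslam_schema(schema_path)
        out = df[[native for _, native in mapping]].copy()
        out.columns = [header for header, _ in mapping]
    elif schema == "native":
        out = df
    else:
        raise ValueError(f"unknown output schema {schema!r}")
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return out
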