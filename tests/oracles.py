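"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the package's own counting/fitting code paths:
the pileup walker re-reads the SAM text directly, the piecewise fitter
enumerates breakpoints with an explicit design matrix and lstsq, and the
grid search scans the exact mixture log-likelihood.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy import stats

_COMP = str.maketrans("ACGTN", "TGCAN")


def read_fasta(path):
    seqs, name, chunks = {}, None, []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks)
                name, chunks = line[1:].split()[0], []
            else:
                chunks.append(line)
    if name is not None:
        seqs[name] = "".join(chunks)
    return seqs


def pileup_counts(sam_path, fasta_path, gene_of_read, strand_of_gene,
                  mask=frozenset(), trim5=0, trim3=0, q_floor=0):
    """Per-read (n_T, k) by walking SAM lines against the reference.

    Only handles the simulator's full-match single-block records; the read
    sequence in SAM is reference-strand, so a reverse-flag read's sequencing
    position p maps to stored offset L-1-p.
    """
    ref = read_fasta(fasta_path)
    out = {}
    with open(sam_path) as fh:
        for line in fh:
            if line.startswith("@"):
                continue
            f = line.rstrip("\n").split("\t")
            qname, flag, chrom, pos = f[0], int(f[1]), f[2], int(f[3]) - 1
            seq, qual = f[9], f[10]
            if flag & 4 or qname not in gene_of_read:
                continue
            gene = gene_of_read[qname]
            gstrand = strand_of_gene[gene]
            L = len(seq)
            n_t = k = 0
            for off in range(L):
                rpos = pos + off
                refbase = ref[chrom][rpos]
                want = "T" if gstrand == "+" else "A"
                if refbase != want:
                    continue
                if (chrom, rpos) in mask:
                    continue
                seq_pos = L - 1 - off if flag & 16 else off
                if seq_pos < trim5 or seq_pos >= L - trim3:
                    continue
                if ord(qual[off]) - 33 < q_floor:
                    continue
                base = seq[off]
                if base == "N":
                    continue
                sense = base if gstrand == "+" else base.translate(_COMP)
                n_t += 1
                if sense == "C":
                    k += 1
            out[qname] = (out.get(qname, (0, 0))[0] + n_t, out.get(qname, (0, 0))[1] + k)
    return out


def piecewise_rss_bruteforce(x, y, m, min_seg=2):
    """Exhaustive continuous piecewise-linear LSQ via explicit hinge design.

    Returns (best_rss, best interior knot indices).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    best = (np.inf, None)
    for combo in combinations(range(min_seg, n - min_seg + 1), m - 1):
        if any(b - a < min_seg for a, b in zip(combo, combo[1:])):
            continue
        knots = [x[0]] + [x[i] for i in combo] + [x[-1]]
        # design: value at each knot, linear interpolation between
        A = np.zeros((n, m + 1))
        seg = np.searchsorted(knots, x, side="right") - 1
        seg = np.clip(seg, 0, m - 1)
        for i in range(n):
            j = seg[i]
            u = (x[i] - knots[j]) / (knots[j + 1] - knots[j])
            A[i, j] = 1 - u
            A[i, j + 1] = u
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        rss = float(((A @ coef - y) ** 2).sum())
        if rss < best[0] - 1e-12:
            best = (rss, combo)
    return best


def grid_search_pi(n, k, w, p_new, p_old, step=1e-3):
    grid = np.arange(0.0, 1.0 + step / 2, step)
    a = stats.binom.pmf(k, n, p_new)
    b = stats.binom.pmf(k, n, p_old)
    with np.errstate(divide="ignore"):
        ll = (w * np.log(np.maximum(grid[:, None] * a + (1 - grid[:, None]) * b, 1e-300))).sum(axis=1)
    return float(grid[np.argmax(ll)])
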