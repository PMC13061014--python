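"""Exhaustive grid search of the binomial-mixture log-likelihood, kept
independent of the package's EM path as a cross-check."""

from __future__ import annotations

import numpy as np
from scipy import stats


def grid_search_pi(n, k, w, p_new, p_old, step=1e-3):
    grid = np.arange(0.0, 1.0 + step / 2, step)
    a = stats.binom.pmf(k, n, p_new)
    b = stats.binom.pmf(k, n, p_old)
    with np.errstate(divide="ignore"):
        ll = (
            w * np.log(np.maximum(grid[:, None] * a + (1 - grid[:, None]) * b, 1e-300))
        ).sum(axis=1)
    return float(grid[np.argmax(ll)])
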