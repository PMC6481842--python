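"""Method-agreement statistics: likelihood-ratio g-test and simple
binomial proportion intervals for naive occupancy."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2
from scipy.special import xlogy

__all__ = ["ContingencyTable", "g_test", "proportion_interval"]


@dataclass(frozen=True)
class ContingencyTable:
    """r x c table of nonnegative integer counts with optional labels."""

    counts: np.ndarray
    row_labels: tuple = ()
    col_labels: tuple = ()

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if counts.ndim != 2:
            raise ValueError("contingency table must be 2-dimensional")
        if (counts < 0).any() or not np.allclose(counts, np.round(counts)):
            raise ValueError("counts must be nonnegative integers")
        if counts.sum() <= 0:
            raise ValueError("table total must be positive")
        object.__setattr__(self, "counts", counts)


def g_test(table: ContingencyTable):
    """Likelihood-ratio (G) test of independence.

    G = 2 sum O ln(O/E) with expected counts from the row/column
    margins; zero cells contribute 0; df = (r-1)(c-1); p-value from the
    chi-square distribution.  No continuity correction is applied.
    """
    O = table.counts
    row = O.sum(axis=1, keepdims=True)
    col = O.sum(axis=0, keepdims=True)
    if (row == 0).any() or (col == 0).any():
        raise ValueError("degenerate table: a row or column margin is zero")
    E = row * col / O.sum()
    G = float(2.0 * xlogy(O, O / E).sum())
    df = (O.shape[0] - 1) * (O.shape[1] - 1)
    p = float(chi2.sf(G, df)) if df > 0 else 1.0
    return G, df, p


def proportion_interval(successes: int, n: int, z: float = 1.0):
    """Wald interval p_hat +/- z * sqrt(p_hat (1 - p_hat) / n), truncated
    to [0, 1].  With z = 1 this is a +/- 1 SE band, not a 95% interval."""
    if not 0 <= successes <= n or n < 1:
        raise ValueError("need 0 <= successes <= n and n >= 1")
    p = successes / n
    half = z * np.sqrt(p * (1.0 - p) / n)
    return p, max(0.0, p - half), min(1.0, p + half)
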