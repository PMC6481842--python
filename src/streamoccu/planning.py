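"""Cumulative detection probability and replicate planning.

Given a single-replicate detection probability p (one survey, or one
filtered water sample), the chance of at least one detection in n
independent replicates at an occupied site is

    p* = 1 - (1 - p)^n

which underpins "how many replicates do I need for 95% confidence the
species is detected if present".
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

__all__ = ["cumulative_detection", "min_replicates", "cumulative_curve"]


def cumulative_detection(p: float, n: int) -> float:
    """p* = 1 - (1 - p)^n, the probability of >= 1 detection in n
    independent replicates, assuming the species is present."""
    if not 0.0 < p <= 1.0:
        raise ValueError(f"p must be in (0, 1], got {p}")
    if int(n) != n or n < 1:
        raise ValueError(f"n must be an integer >= 1, got {n}")
    return 1.0 - (1.0 - p) ** int(n)


def min_replicates(p: float, target: float) -> int:
    """Smallest n with cumulative detection >= target.

    n = ceil(log(1 - target) / log(1 - p)), minimum 1; p = 1 detects on
    the first replicate.
    """
    if not 0.0 < p <= 1.0:
        raise ValueError(f"p must be in (0, 1], got {p}")
    if not 0.0 < target < 1.0:
        raise ValueError(f"target must be in (0, 1), got {target}")
    if p == 1.0:
        return 1
    n = math.ceil(math.log1p(-target) / math.log1p(-p))
    # guard against floating error at exact-hit boundaries
    n = max(n, 1)
    while cumulative_detection(p, n) < target:
        n += 1
    while n > 1 and cumulative_detection(p, n - 1) >= target:
        n -= 1
    return n


def cumulative_curve(p: float, lower: float, upper: float,
                     n_max: int = 10) -> pd.DataFrame:
    """Cumulative detection for n = 1..n_max with an uncertainty band.

    The interval endpoints of the single-replicate p are pushed through
    the (monotone) cumulative map, so lower <= point <= upper for all n
    and the whole band tends to 1 as n grows.
    """
    for name, v in (("lower", lower), ("p", p), ("upper", upper)):
        if not 0.0 < v < 1.0:
            raise ValueError(f"{name} must be in (0, 1), got {v}")
    if not lower <= p <= upper:
        raise ValueError("need lower <= p <= upper")
    ns = np.arange(1, int(n_max) + 1)
    return pd.DataFrame({
        "n": ns,
        "p_star": 1.0 - (1.0 - p) ** ns,
        "lower": 1.0 - (1.0 - lower) ** ns,
        "upper": 1.0 - (1.0 - upper) ** ns,
    })
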