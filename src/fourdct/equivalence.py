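"""Paired TOST (two one-sided tests) equivalence procedure.

Used to establish that respiratory metrics (period, amplitude, irregularity)
measured under the two scan modes in the same patients are practically
equivalent: the paired mean difference is tested against +/- a margin set to
a fraction (default 5%) of the pooled mean of both groups, and equivalence is
declared when both one-sided paired t-tests reject at the chosen alpha.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.stats.weightstats import ttost_paired

from .errors import InsufficientDataError, InvalidParameterError

__all__ = ["TOSTResult", "tost_paired"]


@dataclass(frozen=True)
class TOSTResult:
    mean_difference: float
    equivalence_margin: float
    p_lower: float
    p_upper: float
    equivalent: bool
    n_pairs: int
    alpha: float
    degenerate: bool = False


def tost_paired(
    values_a,
    values_b,
    margin_fraction: float = 0.05,
    alpha: float = 0.05,
) -> TOSTResult:
    """Paired-sample TOST with a margin relative to the pooled mean.

    Parameters
    ----------
    values_a, values_b : array-like
        Equal-length paired measurements (e.g., per-patient mean periods under
        each scan mode). At least 3 pairs.
    margin_fraction : float
        Equivalence margin as a fraction of the mean of all values in both
        groups (0.05 reproduces a conservative "5% of the mean" margin).
    alpha : float
        One-sided significance level for each of the two tests.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise InvalidParameterError("values_a and values_b must be equal-length 1-D")
    if a.size < 3:
        raise InsufficientDataError("need at least 3 pairs for a paired TOST")
    if margin_fraction <= 0:
        raise InvalidParameterError("margin_fraction must be positive")
    pooled_mean = float(np.mean(np.concatenate([a, b])))
    margin = margin_fraction * abs(pooled_mean)
    if margin == 0:
        raise InvalidParameterError("pooled mean is zero; margin undefined")
    diff = a - b
    mean_diff = float(diff.mean())
    if float(diff.std(ddof=1)) == 0.0:
        # all pairs identical shifts: the t statistic is undefined
        inside = abs(mean_diff) < margin
        p = 0.0 if inside else 1.0
        return TOSTResult(
            mean_difference=mean_diff,
            equivalence_margin=margin,
            p_lower=p,
            p_upper=p,
            equivalent=inside,
            n_pairs=a.size,
            alpha=alpha,
            degenerate=True,
        )
    _, lower, upper = ttost_paired(a, b, -margin, margin)
    p_lower, p_upper = float(lower[1]), float(upper[1])
    return TOSTResult(
        mean_difference=mean_diff,
        equivalence_margin=margin,
        p_lower=p_lower,
        p_upper=p_upper,
        equivalent=max(p_lower, p_upper) < alpha,
        n_pairs=a.size,
        alpha=alpha,
    )
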