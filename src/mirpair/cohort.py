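"""Group-comparability statistics for a two-arm study cohort.

Small-sample descriptive inference of the kind reported alongside paired
intervention studies: t-based 95% confidence half-widths for continuous
demographics, two-sided t-tests between arms, and the two-sided Fisher
exact test for 2x2 count tables (e.g. sex by arm).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ValidationError

log = logging.getLogger(__name__)

__all__ = ["GroupSummary", "ci_halfwidth", "two_sided_t_test", "fisher_exact_2x2"]


@dataclass(frozen=True)
class GroupSummary:
    """Sufficient statistics for one group: size, mean and sample sd (n-1)."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValidationError(f"group size must be >= 2, got {self.n}")
        if self.sd < 0:
            raise ValidationError(f"sd must be non-negative, got {self.sd}")


def ci_halfwidth(summary: GroupSummary, level: float = 0.95) -> float:
    """Half-width of the t-based confidence interval for the group mean.

    Computed as ``t_{1-(1-level)/2, n-1} * sd / sqrt(n)``.
    """
    if not 0 < level < 1:
        raise ValidationError(f"confidence level must be in (0, 1), got {level}")
    tcrit = stats.t.ppf(1 - (1 - level) / 2, summary.n - 1)
    return float(tcrit * summary.sd / np.sqrt(summary.n))


def _as_summary(x) -> GroupSummary:
    if isinstance(x, GroupSummary):
        return x
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise ValidationError("raw group data must be 1-D with at least 2 values")
    return GroupSummary(n=int(arr.size), mean=float(arr.mean()), sd=float(arr.std(ddof=1)))


def two_sided_t_test(a, b, pooled: bool = False) -> float:
    """Two-sided t-test p-value between two groups.

    Accepts :class:`GroupSummary` objects or raw 1-D samples.  Welch's
    unequal-variance statistic with Welch–Satterthwaite degrees of freedom
    is the default; ``pooled=True`` uses the classical equal-variance test.
    Two groups with zero variance and equal means return p = 1 by convention.
    """
    sa, sb = _as_summary(a), _as_summary(b)
    va, vb = sa.sd**2, sb.sd**2
    if va == 0 and vb == 0:
        if sa.mean == sb.mean:
            log.warning("both groups have zero variance and equal means; p = 1 by convention")
            return 1.0
        return 0.0
    if pooled:
        df = sa.n + sb.n - 2
        sp2 = ((sa.n - 1) * va + (sb.n - 1) * vb) / df
        se = np.sqrt(sp2 * (1 / sa.n + 1 / sb.n))
    else:
        wa, wb = va / sa.n, vb / sb.n
        se = np.sqrt(wa + wb)
        df = (wa + wb) ** 2 / (wa**2 / (sa.n - 1) + wb**2 / (sb.n - 1))
    tstat = (sa.mean - sb.mean) / se
    return float(2 * stats.t.sf(abs(tstat), df))


def fisher_point_masses(row1: int, row2: int, col1: int):
    """Hypergeometric point masses over all 2x2 tables with the given margins.

    Returns ``(ks, pmf)`` where ``ks`` are the feasible upper-left cell
    counts and ``pmf`` their probabilities under fixed margins.
    """
    n_total = row1 + row2
    k_lo = max(0, col1 - row2)
    k_hi = min(row1, col1)
    ks = np.arange(k_lo, k_hi + 1)
    pmf = stats.hypergeom.pmf(ks, n_total, row1, col1)
    return ks, pmf


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact test p-value for a 2x2 count table.

    Two-sidedness follows the "point mass at most that of the observed
    table" rule: the p-value sums the probabilities of all tables (with
    the observed margins) whose probability does not exceed the observed
    table's.  Any zero margin makes every statistic degenerate; p = 1 by
    convention.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValidationError(f"expected a 2x2 table, got shape {t.shape}")
    if not np.issubdtype(t.dtype, np.integer):
        if not np.allclose(t, np.round(t)):
            raise ValidationError("table entries must be integers")
        t = np.round(t).astype(int)
    if (t < 0).any():
        raise ValidationError("table entries must be non-negative")
    row1, row2 = int(t[0].sum()), int(t[1].sum())
    col1, col2 = int(t[:, 0].sum()), int(t[:, 1].sum())
    if 0 in (row1, row2, col1, col2):
        return 1.0
    ks, pmf = fisher_point_masses(row1, row2, col1)
    observed = stats.hypergeom.pmf(int(t[0, 0]), row1 + row2, row1, col1)
    # small relative slack so ties (incl. the observed table) always count
    keep = pmf <= observed * (1 + 1e-9)
    if keep.all():
        return 1.0
    return float(min(1.0, pmf[keep].sum()))
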