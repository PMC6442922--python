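"""Cross-species gene-set overlap testing by dual-universe permutation.

Two gene sets live in different species' annotation universes and are
compared through an ortholog map (many-to-one, species A -> species B).
Significance of their mapped intersection is assessed by resampling each
set uniformly without replacement from its own universe and recomputing
the mapped overlap, which handles unequal universes and incomplete
ortholog coverage without any distributional assumption.  In the
single-universe limit (identical universes, identity map) the null is
exactly hypergeometric, which :func:`hypergeom_tail` provides as an
analytic oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from scipy import stats
from scipy.special import logsumexp

from .errors import ValidationError

__all__ = [
    "OverlapResult",
    "observed_overlap",
    "permutation_overlap_test",
    "hypergeom_tail",
]


@dataclass(frozen=True)
class OverlapResult:
    """Outcome of a permutation overlap test."""

    observed_overlap: int
    p_value: float
    n_perm: int
    null_mean: float
    null_sd: float
    p_convention: str
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValidationError(f"p-value {self.p_value} outside [0, 1]")


def observed_overlap(
    set_a: Iterable[str], set_b: Iterable[str], ortholog_map: Mapping[str, str]
) -> int:
    """Size of the intersection of ``set_a``'s mapped image with ``set_b``.

    The ortholog map may be many-to-one; images collapse before
    intersecting, and unmapped members of ``set_a`` contribute nothing.
    """
    image = {ortholog_map[g] for g in set_a if g in ortholog_map}
    return len(image & set(set_b))


def _index_map(universe_a, universe_b, ortholog_map):
    """Integer encoding of the map: per index of universe_a, a universe_b index or -1."""
    idx_b = {g: i for i, g in enumerate(universe_b)}
    arr = np.full(len(universe_a), -1, dtype=np.int64)
    for i, g in enumerate(universe_a):
        tgt = ortholog_map.get(g)
        if tgt is not None and tgt in idx_b:
            arr[i] = idx_b[tgt]
    return arr


def permutation_overlap_test(
    set_a,
    set_b,
    universe_a,
    universe_b,
    ortholog_map: Mapping[str, str] | None = None,
    n_perm: int = 10_000,
    seed: int | None = None,
    p_convention: str = "plus_one",
    return_null: bool = False,
):
    """Permutation test of the mapped overlap between two gene sets.

    Each permutation draws a set of size ``|set_a|`` uniformly without
    replacement from ``universe_a`` and one of size ``|set_b|`` from
    ``universe_b`` and recomputes the mapped overlap; ties with the
    observed value count into the upper tail.  ``ortholog_map=None``
    means the identity map restricted to ``universe_b``.

    The ``plus_one`` convention reports ``(#{null >= obs} + 1)/(n_perm + 1)``
    (never exactly zero); ``raw`` reports ``#{null >= obs}/n_perm``.
    """
    if p_convention not in ("plus_one", "raw"):
        raise ValidationError(f"unknown p-value convention {p_convention!r}")
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    universe_a = list(dict.fromkeys(universe_a))
    universe_b = list(dict.fromkeys(universe_b))
    set_a, set_b = set(set_a), set(set_b)
    if not set_a <= set(universe_a):
        raise ValidationError("set_a is not contained in universe_a")
    if not set_b <= set(universe_b):
        raise ValidationError("set_b is not contained in universe_b")
    if ortholog_map is None:
        in_b = set(universe_b)
        ortholog_map = {g: g for g in universe_a if g in in_b}

    obs = observed_overlap(set_a, set_b, ortholog_map)

    map_arr = _index_map(universe_a, universe_b, ortholog_map)
    n_a, n_b = len(universe_a), len(universe_b)
    k_a, k_b = len(set_a), len(set_b)
    rng = np.random.default_rng(seed)
    b_mask = np.zeros(n_b, dtype=bool)
    null = np.empty(n_perm, dtype=np.int64)
    for i in range(n_perm):
        a_star = rng.choice(n_a, size=k_a, replace=False)
        b_star = rng.choice(n_b, size=k_b, replace=False)
        b_mask[b_star] = True
        mapped = map_arr[a_star]
        mapped = np.unique(mapped[mapped >= 0])
        null[i] = np.count_nonzero(b_mask[mapped])
        b_mask[b_star] = False

    exceed = int(np.count_nonzero(null >= obs))
    if p_convention == "plus_one":
        p = (exceed + 1) / (n_perm + 1)
    else:
        p = exceed / n_perm
    result = OverlapResult(
        observed_overlap=obs,
        p_value=float(p),
        n_perm=n_perm,
        null_mean=float(null.mean()),
        null_sd=float(null.std(ddof=1)) if n_perm > 1 else 0.0,
        p_convention=p_convention,
        seed=seed,
    )
    return (result, null) if return_null else result


def hypergeom_tail(k: int, N: int, K: int, n: int) -> float:
    """Exact upper tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    ``N`` is the universe size, ``K`` the number of marked genes and ``n``
    the draw size.  Summation is done in log space for stability.  The
    oracle for the permutation test's identity-universe limit.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValidationError(f"infeasible hypergeometric parameters N={N}, K={K}, n={n}")
    hi = min(K, n)
    if not 0 <= k <= hi + 1:
        raise ValidationError(f"k={k} outside feasible range [0, {hi + 1}]")
    if k == 0:
        return 1.0
    if k > hi:
        return 0.0
    ks = np.arange(k, hi + 1)
    logs = stats.hypergeom.logpmf(ks, N, K, n)
    return float(min(1.0, np.exp(logsumexp(logs))))
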