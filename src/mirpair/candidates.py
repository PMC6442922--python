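"""Candidate miRNA selection from the differential-expression table.

Three filters, applied conjunctively to each tested miRNA:

* FDR: BH-adjusted q-value below the threshold (default 0.05);
* fold: the ratio of arm-level post/pre folds, r = perf_fold/ctrl_fold,
  satisfies max(r, 1/r) >= 1.3 — i.e. at least a 1.3-fold change over
  time in the intervention arm relative to control, either direction;
* delta: at least a 15% relative change of the intervention arm's
  normalized mean from pre to post, |post - pre| / pre >= 0.15.

All bounds are inclusive.  Folds are computed from normalized arm-level
means (not GLM coefficients) because the percentage-change criterion is a
statement about mean expression levels.  Direction is the sign of the
interaction log-fold-change.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

log = logging.getLogger(__name__)

__all__ = ["CandidateSets", "select_candidates"]


@dataclass(frozen=True)
class CandidateSets:
    """Up- and down-regulated candidate miRNAs and the thresholds used."""

    up: frozenset[str]
    down: frozenset[str]
    thresholds: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.up & self.down:
            raise ValidationError("a miRNA cannot be both up- and down-regulated")

    @property
    def all_ids(self) -> frozenset[str]:
        return self.up | self.down

    def direction_of(self, mirna_id: str) -> str:
        if mirna_id in self.up:
            return "up"
        if mirna_id in self.down:
            return "down"
        raise KeyError(mirna_id)


def select_candidates(
    de: pd.DataFrame,
    fdr: float = 0.05,
    fold: float = 1.3,
    delta: float = 0.15,
) -> CandidateSets:
    """Apply the FDR / fold-ratio / percent-change filters to a DE table.

    ``de`` must be indexed by miRNA id with columns ``q_value``,
    ``interaction_lfc``, ``perf_post_pre_fold`` and ``ctrl_post_pre_fold``.
    miRNAs with an undefined pre-session mean in the intervention arm
    (fold of 0/0 or division by zero) are excluded with a warning.
    """
    required = {"q_value", "interaction_lfc", "perf_post_pre_fold", "ctrl_post_pre_fold"}
    missing = required - set(de.columns)
    if missing:
        raise ValidationError(f"DE table missing columns: {sorted(missing)}")

    q = de["q_value"].to_numpy(dtype=float)
    pf = de["perf_post_pre_fold"].to_numpy(dtype=float)
    cf = de["ctrl_post_pre_fold"].to_numpy(dtype=float)
    lfc = de["interaction_lfc"].to_numpy(dtype=float)

    defined = np.isfinite(q) & np.isfinite(pf) & np.isfinite(cf) & (pf > 0) & (cf > 0)
    n_undef = int((~defined & ~np.isnan(q)).sum())
    if n_undef:
        log.warning("%d tested miRNAs excluded: undefined post/pre folds", n_undef)

    with np.errstate(divide="ignore", invalid="ignore"):
        r = pf / cf
        fold_ok = np.maximum(r, 1.0 / r) >= fold
        # perf fold F = post/pre, so |post-pre|/pre == |F - 1|
        delta_ok = np.abs(pf - 1.0) >= delta
    keep = defined & (q < fdr) & fold_ok & delta_ok

    ids = de.index.to_numpy()
    up = frozenset(ids[keep & (lfc > 0)])
    down = frozenset(ids[keep & (lfc < 0)])
    return CandidateSets(
        up=up, down=down, thresholds={"fdr": fdr, "fold": fold, "delta": delta}
    )
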