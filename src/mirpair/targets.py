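"""Filtering and merging of miRNA target tables.

Predicted targets (TargetScan-style records with a miRNA family
conservation class, a site conservation class, an aggregate probability
of conserved targeting PCT and a total context++ repression score) are
filtered by conservation-dependent rules; validated targets
(miRTarBase-style records) are admitted only with strong experimental
evidence (reporter assay or western blot).

Filter rules for predicted records:

* conserved / broadly conserved family: keep iff the site is conserved
  AND PCT >= 0.2 AND context++ <= -0.15 (both bounds inclusive);
* poorly conserved / other family: keep iff context++ < -0.15 (strict);
* non-canonical binding sites are always dropped.

The asymmetry between the inclusive -0.15 bound for conserved families
and the strict one for poorly conserved families is deliberate and
preserved exactly.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .candidates import CandidateSets
from .errors import ValidationError

log = logging.getLogger(__name__)

__all__ = [
    "validate_target_records",
    "filter_predicted",
    "merge_validated",
    "targets_by_direction",
]

TARGET_COLUMNS = [
    "mirna_id", "family_class", "gene_id", "site_class", "pct", "contextpp",
    "source", "evidence",
]
_FAMILY = {"conserved", "broadly_conserved", "poorly_conserved", "other"}
_SITE = {"conserved", "nonconserved", "non_canonical"}
_EVIDENCE = {"reporter_assay", "western_blot", "weak", "none"}


def validate_target_records(records: pd.DataFrame) -> pd.DataFrame:
    """Validate a target table and normalize gene symbols to upper case."""
    missing = set(TARGET_COLUMNS) - set(records.columns)
    if missing:
        raise ValidationError(f"target table missing columns: {sorted(missing)}")
    out = records.copy()
    if len(out) == 0:
        return out
    for col, allowed in (("family_class", _FAMILY), ("site_class", _SITE),
                         ("evidence", _EVIDENCE)):
        bad = set(out[col].dropna()) - allowed
        if bad:
            raise ValidationError(f"unknown {col} values: {sorted(bad)}")
    pct = out["pct"].to_numpy(dtype=float)
    if np.nanmin(pct, initial=0.0) < 0 or np.nanmax(pct, initial=0.0) > 1:
        raise ValidationError("pct values must lie in [0, 1]")
    # gene identity is by symbol, case-normalized (inputs mix species conventions)
    out["gene_id"] = out["gene_id"].astype(str).str.upper()
    return out


def filter_predicted(records: pd.DataFrame) -> pd.DataFrame:
    """Apply the conservation/score filter to predicted target records."""
    rec = validate_target_records(records)
    rec = rec[rec["source"] == "predicted"]
    if len(rec) == 0:
        return rec

    no_cpp = rec["contextpp"].isna()
    if no_cpp.any():
        log.warning("%d predicted records dropped: missing context++ score", no_cpp.sum())
        rec = rec[~no_cpp]

    fam = rec["family_class"]
    conserved_fam = fam.isin(["conserved", "broadly_conserved"])
    pct = rec["pct"].to_numpy(dtype=float)
    cpp = rec["contextpp"].to_numpy(dtype=float)

    missing_pct = conserved_fam & rec["pct"].isna()
    if missing_pct.any():
        log.warning(
            "%d conserved-family records dropped: missing PCT", int(missing_pct.sum())
        )

    with np.errstate(invalid="ignore"):
        keep_conserved = (
            conserved_fam
            & (rec["site_class"] == "conserved")
            & (pct >= 0.2)
            & (cpp <= -0.15)
        )
        keep_other = ~conserved_fam & (cpp < -0.15)
    keep = (keep_conserved | keep_other) & (rec["site_class"] != "non_canonical")
    return rec[keep].reset_index(drop=True)


def merge_validated(predicted_kept: pd.DataFrame, validated_records: pd.DataFrame) -> pd.DataFrame:
    """Union of filtered predictions with strong-evidence validated targets.

    Records are keyed on (mirna_id, gene_id); a pair present in both
    sources is kept once with ``source="both"``.  Validated records with
    only weak evidence are excluded.
    """
    val = validate_target_records(validated_records)
    val = val[val["source"] == "validated"]
    val = val[val["evidence"].isin(["reporter_assay", "western_blot"])]
    pred = validate_target_records(predicted_kept) if len(predicted_kept) else predicted_kept

    merged = pd.concat([pred, val], ignore_index=True)
    if len(merged) == 0:
        return merged
    key = ["mirna_id", "gene_id"]
    n_sources = merged.groupby(key)["source"].transform("nunique")
    merged = merged.assign(
        source=np.where(n_sources > 1, "both", merged["source"])
    )
    return merged.drop_duplicates(subset=key, keep="first").reset_index(drop=True)


def targets_by_direction(
    candidates: CandidateSets, target_set: pd.DataFrame
) -> dict[str, set[str]]:
    """Per-direction union of target genes over each direction's miRNAs."""
    rec = validate_target_records(target_set) if len(target_set) else target_set
    known = set(rec["mirna_id"]) if len(rec) else set()
    out: dict[str, set[str]] = {}
    for direction, ids in (("up", candidates.up), ("down", candidates.down)):
        absent = ids - known
        if absent:
            log.warning(
                "%d %s-regulated candidate miRNAs absent from target table", len(absent), direction
            )
        present = ids & known
        if present:
            out[direction] = set(rec.loc[rec["mirna_id"].isin(present), "gene_id"])
        else:
            out[direction] = set()
    return out
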