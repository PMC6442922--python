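#!/usr/bin/env python
"""Target-gene filtering for the candidate miRNAs.

Predicted records pass the conservation-dependent score filter
(conserved families: conserved site, PCT >= 0.2, context++ <= -0.15;
poorly conserved: context++ < -0.15; non-canonical sites dropped);
validated records need strong evidence (reporter assay / western blot).
Writes the merged table and the per-direction target gene sets.
"""

from pathlib import Path

import pandas as pd

from mirpair import filter_predicted, merge_validated, targets_by_direction, io
from mirpair.candidates import CandidateSets

ROOT = Path(__file__).resolve().parents[1]
SIM = ROOT / "results" / "sim"
OUT = ROOT / "results"


def main() -> None:
    predicted = io.read_targets_tsv(SIM / "predicted_targets.tsv")
    validated = io.read_targets_tsv(SIM / "validated_targets.tsv")
    cand_df = pd.read_csv(OUT / "candidates.tsv", sep="\t")
    cands = CandidateSets(
        up=frozenset(cand_df.loc[cand_df["direction"] == "up", "mirna_id"]),
        down=frozenset(cand_df.loc[cand_df["direction"] == "down", "mirna_id"]),
    )

    kept = filter_predicted(predicted)
    merged = merge_validated(kept, validated)
    io.write_targets_tsv(merged, OUT / "targets_filtered.tsv")
    print(f"{len(predicted)} predicted records -> {len(kept)} after the score filter")
    print(f"+ strong-evidence validated records -> {len(merged)} merged interactions")

    by_dir = targets_by_direction(cands, merged)
    io.write_gmt({f"targets_{d}": g for d, g in by_dir.items() if g},
                 OUT / "targets_by_direction.gmt")
    for d in ("up", "down"):
        print(f"target genes of {d}-regulated candidates: {len(by_dir.get(d, set()))}")
    print(f"wrote {OUT / 'targets_filtered.tsv'} and {OUT / 'targets_by_direction.gmt'}")


if __name__ == "__main__":
    main()
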