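#!/usr/bin/env python
"""Candidate miRNA selection from the DE table.

Keeps miRNAs with q < 0.05, at least a 1.3-fold post/pre change over
time relative to control (either direction), and at least a 15%
relative change of the intervention arm's mean; writes
results/candidates.tsv with directions.
"""

from pathlib import Path

import pandas as pd

from mirpair import select_candidates

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results"


def main() -> None:
    de = pd.read_csv(OUT / "de_results.tsv", sep="\t", index_col=0)
    cands = select_candidates(de, fdr=0.05, fold=1.3, delta=0.15)
    rows = [(m, "up") for m in sorted(cands.up)] + \
           [(m, "down") for m in sorted(cands.down)]
    pd.DataFrame(rows, columns=["mirna_id", "direction"]).to_csv(
        OUT / "candidates.tsv", sep="\t", index=False
    )
    n_sig = int((de["q_value"] < 0.05).sum())
    print(f"{n_sig} miRNAs at q < 0.05; after the fold (>=1.3) and "
          f"15%-change filters: {len(cands.up)} up-regulated, "
          f"{len(cands.down)} down-regulated candidates")
    print(f"wrote {OUT / 'candidates.tsv'}")


if __name__ == "__main__":
    main()
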