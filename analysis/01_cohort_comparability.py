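#!/usr/bin/env python
"""Group comparability of the two study arms from published summary statistics.

Reads the per-arm demographic summaries (mean, sd, n) and 2x2 count
tables from data/, computes t-based 95% confidence half-widths, Welch
two-sided t-tests and two-sided Fisher exact tests, and writes
results/cohort_stats.tsv.
"""

from pathlib import Path

import pandas as pd

from mirpair import GroupSummary, ci_halfwidth, fisher_exact_2x2, two_sided_t_test

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results"
OUT.mkdir(exist_ok=True)


def main() -> None:
    summaries = pd.read_csv(ROOT / "data" / "cohort_summaries.csv")
    rows = []
    for var, grp in summaries.groupby("variable", sort=False):
        groups = {
            r.group: GroupSummary(n=int(r.n), mean=float(r.mean), sd=float(r.sd))
            for r in grp.itertuples(index=False)
        }
        p = two_sided_t_test(groups["performance"], groups["control"])
        for name, g in groups.items():
            rows.append({
                "variable": var, "group": name, "n": g.n, "mean": g.mean,
                "sd": g.sd, "ci95_halfwidth": round(ci_halfwidth(g), 2),
                "welch_p": round(p, 4),
            })
        verdict = "similar" if p >= 0.05 else "different"
        print(f"{var}: performance {groups['performance'].mean} ± "
              f"{groups['performance'].sd} vs control {groups['control'].mean} ± "
              f"{groups['control'].sd}; Welch p = {p:.4f} ({verdict} at the 5% level)")

    counts = pd.read_csv(ROOT / "data" / "cohort_counts.csv")
    for r in counts.itertuples(index=False):
        p = fisher_exact_2x2([[r.a, r.b], [r.c, r.d]])
        rows.append({"variable": r.variable, "group": "both", "n": r.a + r.b + r.c + r.d,
                     "mean": None, "sd": None, "ci95_halfwidth": None,
                     "welch_p": None, "fisher_p": round(p, 4)})
        print(f"{r.variable}: [[{r.a},{r.b}],[{r.c},{r.d}]] Fisher exact p = {p:.4f}")

    pd.DataFrame(rows).to_csv(OUT / "cohort_stats.tsv", sep="\t", index=False)
    print(f"\nwrote {OUT / 'cohort_stats.tsv'}")


if __name__ == "__main__":
    main()
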