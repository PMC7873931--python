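#!/usr/bin/env python
"""Relate the six relative-area parameters to each other and to the levels.

On the scored cohort: Pearson correlations between the surface parameters
(standard, FP/RA1, DP/RA1, DP/RA2, FULL), fixed-effects ANOVA of each
parameter over the standard levels with Tukey-Kramer pairwise comparisons,
and the relative metatarsal-pad size per level.  Writes
results/analysis/surface_correlations.csv and level_comparisons.csv.
"""

from pathlib import Path

import pandas as pd

from fpdkit import association, pipeline, synth

SEED = 42
OUT = Path("results/analysis")
PARAMS = ["standard", "fp_ra1", "dp_ra1", "dp_ra2", "full", "rel_met"]


def main() -> None:
    scored = OUT / "scored_cohort.csv"
    if scored.exists():
        df = pd.read_csv(scored)
        df["error"] = df["error"].fillna("")
    else:
        samples = synth.generate_cohort(synth.CohortSpec(n_per_level=100, seed=SEED))
        df = pipeline.score_cohort(samples)
    ok = df[df["error"] == ""]

    rows = []
    for a, b in pipeline.CORRELATION_PAIRS:
        r, p = association.correlate(ok[a], ok[b])
        rows.append({"pair": f"{a} ~ {b}", "r_p": r, "p": p})
    corr = pd.DataFrame(rows)
    OUT.mkdir(parents=True, exist_ok=True)
    corr.to_csv(OUT / "surface_correlations.csv", index=False)
    print("Pearson correlations between surface parameters:")
    print(corr.round(3).to_string(index=False))

    comp_rows = []
    for name in PARAMS:
        comp = association.compare_levels(ok[name], ok["true_level"])
        sig = [
            f"{g1}-{g2}"
            for g1, g2, rej in zip(
                comp.pairs["group1"], comp.pairs["group2"], comp.pairs["reject"]
            )
            if rej
        ]
        comp_rows.append(
            {
                "parameter": name,
                "F": comp.f_statistic,
                "df1": comp.df1,
                "df2": comp.df2,
                "p": comp.p_value,
                "significant_pairs": ";".join(sig),
            }
        )
        print(
            f"\n{name}: F({comp.df1},{comp.df2}) = {comp.f_statistic:.1f}, "
            f"p = {comp.p_value:.2g}; significant level pairs: {sig}"
        )
    pd.DataFrame(comp_rows).to_csv(OUT / "level_comparisons.csv", index=False)


if __name__ == "__main__":
    main()
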