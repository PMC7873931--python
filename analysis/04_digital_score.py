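#!/usr/bin/env python
"""Condense the six digit variables into one "digital score" per foot.

On the scored cohort: polychoric correlation matrix of the per-digit
lesion and swelling grades -> principal-axis factoring (SMC priors,
minimum eigenvalue 1, varimax) -> regression factor scores.  The digital
score is then related to the standard metatarsal score (Spearman
correlation, one-way ANOVA with Tukey-Kramer pairwise level comparisons)
and the digits are compared with blocked Friedman tests.  Tables go to
results/analysis/.
"""

import json
from pathlib import Path

import pandas as pd

from fpdkit import pipeline, synth

SEED = 42
OUT = Path("results/analysis")


def main() -> None:
    scored = OUT / "scored_cohort.csv"
    if scored.exists():
        df = pd.read_csv(scored)
        df["error"] = df["error"].fillna("")
    else:
        samples = synth.generate_cohort(synth.CohortSpec(n_per_level=100, seed=SEED))
        df = pipeline.score_cohort(samples)
    report = pipeline.analyze_scored(df)

    OUT.mkdir(parents=True, exist_ok=True)
    with open(OUT / "digital_score_report.json", "w") as fh:
        json.dump(report, fh, indent=1)

    print(f"{report['pct_intact_digits']:.1f}% of feet have intact digits")
    dist = pd.DataFrame(report["affected_digits_by_level"]).T
    dist.index.name = "standard level"
    dist.to_csv(OUT / "affected_digits_by_level.csv")
    print("\naffected-digit distribution per level (proportions):")
    print(dist.round(2))

    for kind in ("lesion", "swelling"):
        fr = report[f"friedman_{kind}"]
        print(
            f"\nFriedman ({kind} across digits): "
            f"F({fr['df1']},{fr['df2']}) = {fr['F']:.2f}, p = {fr['p']:.2g}"
        )

    dig = report["digital_score"]
    if "spearman_vs_standard" in dig:
        print(
            f"\nPCA: first eigenvalue {dig['first_eigenvalue']:.2f}, "
            f"{dig['n_retained']} factor(s) retained"
        )
        print(
            f"digital score vs standard level: r_s = "
            f"{dig['spearman_vs_standard']:.2f} (p = {dig['spearman_p']:.2g}); "
            f"ANOVA F({dig['anova_df'][0]},{dig['anova_df'][1]}) = "
            f"{dig['anova_F']:.1f} (p = {dig['anova_p']:.2g})"
        )
        print(f"significant level pairs: {dig['significant_pairs']}")
    else:
        print("digital score unavailable:", dig)


if __name__ == "__main__":
    main()
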