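# fpdkit

Footpad dermatitis (FPD) — a contact dermatitis of the plantar foot surface —
is one of the most widely used animal-welfare indicators in turkey
production.  The standard European five-point score grades only the
*metatarsal pad* by the relative area of its brownish lesions, yet
alterations also occur on the *digital pads* (digits 2–4), where they are
currently ignored.  `fpdkit` is a tested re-implementation of the analysis
chain needed to study that gap with a slaughter-line camera geometry:

* **synthetic imagery** — suspended-foot RGB images on a dark background
  with pixel-exact ground truth (lesion fractions, swelling factors,
  per-level stratified cohorts, noisy ordinal raters, latent-normal ordinal
  data);
* **segmentation** — foot detection by background contrast, metatarsal pad
  vs. digit separation via the interdigital background, per-digit phalanx
  segments at width minima, lesion detection by a brown/dark HSV box;
* **morphometry** — the six relative-area parameters
  `standard = A_met / RA2`, `FP/RA1 = A_met / RA1`, `DP/RA1 = A_dig / RA1`,
  `DP/RA2 = A_dig / RA2`, `FULL = (A_met + A_dig) / RA1`,
  `rel_met = RA2 / RA1`, where `RA1` is the whole visible foot, `RA2` the
  metatarsal pad, and `A` pixel lesion areas;
* **scoring** — the standard five-point rubric
  (0; (0, 10 %); [10 %, 25 %]; (25 %, 50 %]; > 50 %), a five-point
  per-digit lesion score over phalanx-segment fractions, a three-point
  swelling grade against the contralateral digit, the affected-digit count
  and a binomial any-digit flag;
* **reliability** — Krippendorff's alpha `α = 1 − D_o / D_e` from the
  coincidence matrix, with ordinal and interval difference functions and
  Landis–Koch labels;
* **association** — pairwise two-step maximum-likelihood polychoric
  correlations, principal-axis factoring with SMC priors (minimum
  eigenvalue 1, varimax) producing a per-foot "digital score", blocked
  Friedman tests across digits, Pearson/Spearman correlations, and
  Tukey-Kramer pairwise comparisons across score levels.

It is aimed at researchers in poultry-welfare assessment and precision
livestock farming who need a reproducible, fully synthetic benchmark of
this scoring chain.

## Worked example

```python
from fpdkit import synth, pipeline

params = synth.FootGenParams(
    met_lesion_frac=0.30,                       # 30 % of the metatarsal pad
    digit_lesion_fracs={2: (0.6, 0, 0), 3: (0, 0, 0), 4: (0.02, 0.02, 0)},
    swelling_factors={2: 1.0, 3: 1.25, 4: 1.0},  # digit 3 swollen by 25 %
    seed=7,
)
left, right, truth = synth.generate_foot_pair(params)
report, record, masks = pipeline.score_foot_pair(left, right)
print(round(report.standard, 3), record.standard_score)
print(dict(record.digit_lesion_scores), dict(record.swelling_scores))
```

prints

```
0.298 3
{2: 3, 3: 0, 4: 1} {2: 0, 3: 1, 4: 0}
```

— the measured pad lesion fraction (0.298 vs. the generated 0.30) grades as
standard score 3; digit 2's proximal segment covered 60 % → lesion score 3;
digit 4's two punctual spots → score 1; digit 3's 25 % area inflation
relative to the same digit on the reference foot → slight swelling
(grade 1).

The full study runs as numbered drivers:

```bash
python analysis/01_simulate_cohort.py      # 500 feet, 100 per level
python analysis/02_segment_and_score.py    # pipeline + recovery check
python analysis/03_observer_reliability.py # alpha per parameter
python analysis/04_digital_score.py        # polychoric-PCA digital score
python analysis/05_surface_correlations.py # six-parameter correlations
```

with tables under `results/analysis/`.  A thin CLI (`fpdkit simulate`,
`score`, `analyze`, `reliability`) wraps the same library for on-disk
cohorts.

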