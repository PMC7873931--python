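#!/usr/bin/env python
"""Generate the study cohort: 500 synthetic feet, 100 per standard level.

Writes the cohort manifest (with exact ground-truth ratios) to
results/analysis/cohort_manifest.csv and the full image set (PNGs, label
masks, JSON sidecars) to scratch/cohort/ — the images are bulky and
regenerable, so they stay out of the tracked results.
"""

from pathlib import Path

from fpdkit import io as fio
from fpdkit import synth

SEED = 42
OUT = Path("results/analysis")
SCRATCH = Path("scratch/cohort")


def main() -> None:
    spec = synth.CohortSpec(n_per_level=100, seed=SEED)
    samples = synth.generate_cohort(spec)
    manifest = fio.write_cohort(SCRATCH, samples, SEED, fio.config_hash(spec))
    OUT.mkdir(parents=True, exist_ok=True)
    target = OUT / "cohort_manifest.csv"
    target.write_bytes(Path(manifest).read_bytes())
    levels = [s.level for s in samples]
    print(f"wrote {len(samples)} feet to {SCRATCH} (images) and {target} (manifest)")
    for lv in sorted(set(levels)):
        print(f"  level {lv}: {levels.count(lv)} feet")


if __name__ == "__main__":
    main()
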