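"""Disk formats: PNG images, label-mask PNGs, JSON sidecars, CSV manifests.

Images are 8-bit RGB PNG.  Region masks are single-channel label PNGs
(0 = background, 1 = metatarsal pad, 2-4 = digits); the lesion mask is a
separate single-channel PNG with 255 on lesion pixels.  Every manifest
carries the generating seed and a config hash so a run is reproducible
from its outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Iterable, List

import numpy as np
import pandas as pd
from PIL import Image

from .segment import FootMasks
from .synth import FootSample

__all__ = [
    "write_image", "read_image", "write_label_masks", "write_cohort",
    "read_cohort_manifest", "config_hash",
]


def write_image(path: Path, image: np.ndarray) -> None:
    Image.fromarray(np.asarray(image, dtype=np.uint8), mode="RGB").save(path)


def read_image(path: Path) -> np.ndarray:
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def write_label_masks(stem: Path, masks: FootMasks) -> None:
    """Write region labels and the lesion overlay as two grayscale PNGs."""
    labels = np.zeros(masks.foot_mask.shape, dtype=np.uint8)
    labels[masks.metatarsal_mask.astype(bool)] = 1
    for d, m in masks.digit_masks.items():
        labels[m.astype(bool)] = d
    Image.fromarray(labels, mode="L").save(stem.with_suffix(".labels.png"))
    lesion = np.where(masks.lesion_mask.astype(bool), 255, 0).astype(np.uint8)
    Image.fromarray(lesion, mode="L").save(stem.with_suffix(".lesion.png"))


def config_hash(obj) -> str:
    """Stable short hash of a (dataclass or plain) configuration object."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        obj = dataclasses.asdict(obj)
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _truth_sidecar(sample: FootSample) -> dict:
    t = sample.truth
    return {
        "foot_id": sample.foot_id,
        "pair_id": sample.pair_id,
        "flock": sample.flock,
        "side": sample.side,
        "true_level": sample.level,
        "true_ratios": t.true_ratios.as_dict(),
        "true_segment_fractions": t.true_segment_fractions,
        "true_scores": {
            "standard": t.true_scores.standard_score,
            "lesion": dict(t.true_scores.digit_lesion_scores),
            "swelling": dict(t.true_scores.swelling_scores),
            "n_affected": t.true_scores.n_affected_digits,
            "digit_flag": t.true_scores.digit_flag,
        },
        "digit_areas": t.digit_areas,
        "reference_digit_areas": t.reference_digit_areas,
        "latent_severity": t.latent_severity,
        "seed": t.params.seed,
    }


def write_cohort(
    outdir: Path, samples: Iterable[FootSample], seed: int, cfg_hash: str = ""
) -> Path:
    """Write images, masks, JSON sidecars and the manifest CSV for a cohort.

    Returns the manifest path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows: List[dict] = []
    for s in samples:
        write_image(outdir / f"{s.foot_id}.png", s.image)
        write_image(outdir / f"{s.foot_id}.ref.png", s.reference_image)
        write_label_masks(outdir / s.foot_id, s.truth.masks)
        with open(outdir / f"{s.foot_id}.json", "w") as fh:
            json.dump(_truth_sidecar(s), fh, indent=1)
        row = {
            "foot_id": s.foot_id, "pair_id": s.pair_id, "flock": s.flock,
            "side": s.side, "true_level": s.level,
        }
        row.update(
            {f"true_{k}": v for k, v in s.truth.true_ratios.as_dict().items()
             if not k.startswith("px_")}
        )
        rows.append(row)
    manifest = outdir / "manifest.csv"
    df = pd.DataFrame(rows)
    df.attrs["seed"] = seed
    with open(manifest, "w") as fh:
        fh.write(f"# seed={seed} config={cfg_hash}\n")
        df.to_csv(fh, index=False)
    return manifest


def read_cohort_manifest(manifest: Path) -> pd.DataFrame:
    return pd.read_csv(manifest, comment="#")
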