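"""Paired clean/degraded dataset builds.

For each input record the build renders the clean paper image (dataset A),
samples one photographic scene and produces the degraded counterpart
(dataset B), and writes sidecar manifests linking the pair: the render
manifest (pixel geometry), the degradation record (realized homography and
noise parameters) and a dataset-level CSV index.

Reproducibility: one global seed; each record's RNG stream is derived from
(seed, crc32(record_id)), so rebuilding any subset in any order reproduces
identical images.
"""

from __future__ import annotations

import json
import os
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from PIL import Image

from .degrade import degrade_image, sample_scene_config
from .layout import LayoutSpec, RenderSpec
from .records import ECGRecord
from .render import render_clean_image


@dataclass
class BuildResult:
    index_path: str
    rows: list[dict] = field(default_factory=list)


def record_rng(seed: int, record_id: str) -> np.random.Generator:
    """Per-record RNG stream, independent of processing order."""
    return np.random.default_rng(
        np.random.SeedSequence([seed, zlib.crc32(record_id.encode())])
    )


def save_png(image: np.ndarray, path: str) -> None:
    Image.fromarray(image).save(path, format="PNG")


def build_dataset(
    records: list[ECGRecord],
    out_dir: str,
    seed: int = 0,
    layout: LayoutSpec | None = None,
    render_spec: RenderSpec | None = None,
) -> BuildResult:
    """Render and degrade every record; returns the dataset index."""
    clean_dir = os.path.join(out_dir, "clean")
    degraded_dir = os.path.join(out_dir, "degraded")
    os.makedirs(clean_dir, exist_ok=True)
    os.makedirs(degraded_dir, exist_ok=True)

    rows = []
    for record in records:
        image, manifest = render_clean_image(record, layout, render_spec)
        clean_path = os.path.join(clean_dir, f"{record.record_id}.png")
        save_png(image, clean_path)
        manifest.to_json(os.path.join(clean_dir, f"{record.record_id}.manifest.json"))

        rng = record_rng(seed, record.record_id)
        config = sample_scene_config(rng)
        degraded, deg_record = degrade_image(image, manifest, config)
        degraded_path = os.path.join(degraded_dir, f"{record.record_id}.png")
        save_png(degraded, degraded_path)
        deg_record.to_json(
            os.path.join(degraded_dir, f"{record.record_id}.degradation.json")
        )
        config_hash = f"{zlib.crc32(json.dumps(config.as_dict(), sort_keys=True).encode()):08x}"
        rows.append({
            "record_id": record.record_id,
            "clean_path": os.path.relpath(clean_path, out_dir),
            "degraded_path": os.path.relpath(degraded_path, out_dir),
            "config_hash": config_hash,
            "seed": seed,
        })
    index_path = os.path.join(out_dir, "dataset.csv")
    pd.DataFrame(rows).to_csv(index_path, index=False)
    return BuildResult(index_path=index_path, rows=rows)
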