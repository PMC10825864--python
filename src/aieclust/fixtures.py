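"""Deterministic test-fixture generation.

Writes a small, fully reproducible file tree of synthetic images with
ground-truth sidecar CSVs: a bright disk (segmentation geometry), two
disjoint blobs (component counting), an affine-correlated and an
anti-correlated channel pair (colocalization), and a 3-dose mini
experiment. Everything is derived from one seed.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from ._rng import as_generator
from .aie_optics import MicroImage
from .config import ExperimentConfig
from .dose_response import run_experiment
from .io import write_image

__all__ = ["make_fixtures"]

_PIXEL_SIZE = 325.0


def _disk_image(shape, center, radius, fg, bg) -> tuple[MicroImage, int]:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    inside = (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2
    px = np.full(shape, float(bg))
    px[inside] = fg
    return MicroImage(pixels=px, pixel_size=_PIXEL_SIZE), int(inside.sum())


def make_fixtures(out_dir, seed: int = 0) -> dict:
    """Write the fixture tree under `out_dir`; returns a manifest of paths."""
    os.makedirs(out_dir, exist_ok=True)
    rng = as_generator(seed)
    manifest = {}

    # 1. bright disk with analytic ground truth
    disk, area_px = _disk_image((96, 96), (48, 48), 30, fg=100.0, bg=10.0)
    p = os.path.join(out_dir, "disk.tif")
    write_image(p, disk)
    pd.DataFrame(
        [{"center_row": 48, "center_col": 48, "radius_px": 30, "area_px": area_px}]
    ).to_csv(os.path.join(out_dir, "disk_truth.csv"), index=False)
    manifest["disk"] = p

    # 2. two disjoint blobs
    blob_a, _ = _disk_image((96, 96), (30, 28), 12, fg=90.0, bg=5.0)
    blob_b, _ = _disk_image((96, 96), (68, 70), 10, fg=90.0, bg=5.0)
    two = MicroImage(pixels=np.maximum(blob_a.pixels, blob_b.pixels), pixel_size=_PIXEL_SIZE)
    p = os.path.join(out_dir, "two_blobs.tif")
    write_image(p, two)
    pd.DataFrame(
        [
            {"center_row": 30, "center_col": 28, "radius_px": 12},
            {"center_row": 68, "center_col": 70, "radius_px": 10},
        ]
    ).to_csv(os.path.join(out_dir, "two_blobs_truth.csv"), index=False)
    manifest["two_blobs"] = p

    # 3. correlated channel pair: B = 2A + 5 (PCC exactly 1)
    a = rng.uniform(10.0, 200.0, size=(64, 64)).astype(np.float32)
    b = (2.0 * a + 5.0).astype(np.float32)
    pa = os.path.join(out_dir, "pair_correlated_A.tif")
    pb = os.path.join(out_dir, "pair_correlated_B.tif")
    write_image(pa, MicroImage(pixels=a.astype(float), pixel_size=_PIXEL_SIZE))
    write_image(pb, MicroImage(pixels=b.astype(float), pixel_size=_PIXEL_SIZE))
    manifest["pair_correlated"] = (pa, pb)

    # 4. anti-correlated pair: B = 300 - A (PCC exactly -1)
    c = rng.uniform(10.0, 200.0, size=(64, 64)).astype(np.float32)
    d = (300.0 - c).astype(np.float32)
    pc = os.path.join(out_dir, "pair_anticorrelated_A.tif")
    pd_ = os.path.join(out_dir, "pair_anticorrelated_B.tif")
    write_image(pc, MicroImage(pixels=c.astype(float), pixel_size=_PIXEL_SIZE))
    write_image(pd_, MicroImage(pixels=d.astype(float), pixel_size=_PIXEL_SIZE))
    manifest["pair_anticorrelated"] = (pc, pd_)

    # 5. 3-dose mini experiment
    config = ExperimentConfig(
        doses=(0.0, 1.0, 100.0),
        times=(24.0,),
        replicates=2,
        cells_per_well=3,
        master_seed=int(np.random.SeedSequence(seed, spawn_key=(99,)).generate_state(1)[0] % (2**31)),
    )
    result = run_experiment(config)
    exp_dir = os.path.join(out_dir, "mini_experiment")
    result.write(exp_dir)
    manifest["mini_experiment"] = exp_dir
    return manifest
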