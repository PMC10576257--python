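"""Disk formats: TIFF stacks, CSV tables, run manifests."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import tifffile

from .kymograph import AxonPath, Kymograph
from .simulate import GroundTruth, MovieStack


def save_movie(path, stack: MovieStack) -> None:
    tifffile.imwrite(str(path), stack.data,
                     metadata={"pixel_size_um": stack.pixel_size,
                               "frame_interval_s": stack.frame_interval})


def load_movie(path, pixel_size: float, frame_interval: float) -> MovieStack:
    data = tifffile.imread(str(path))
    if data.ndim == 2:
        data = data[None]
    return MovieStack(data, pixel_size, frame_interval)


def save_axon_path(path, axon: AxonPath) -> None:
    df = pd.DataFrame(axon.vertices, columns=["x", "y"])
    df.to_csv(str(path), index=False)


def load_axon_path(path, soma_end: str = "start", sampling_width: int = 5) -> AxonPath:
    df = pd.read_csv(str(path))
    return AxonPath(df[["x", "y"]].to_numpy(), soma_end, sampling_width)


def save_ground_truth(path, truth: GroundTruth) -> None:
    truth.trajectories.to_csv(str(path), index=False)


def save_kymograph(path_tif, kym: Kymograph, path_png: Optional[str] = None) -> None:
    tifffile.imwrite(str(path_tif), kym.data.astype(np.float32))
    if path_png is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 4))
        ax.imshow(kym.data, cmap="gray", aspect="auto",
                  extent=[0, kym.length_um, kym.duration_s, 0])
        ax.set_xlabel("position along axon (um, soma at 0)")
        ax.set_ylabel("time (s)")
        fig.savefig(path_png, dpi=120)
        plt.close(fig)


def sha256_of(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(path, *, config: dict, seed: Optional[int], outputs,
                   version: str) -> dict:
    manifest = {
        "version": version,
        "seed": seed,
        "config": config,
        "outputs": {str(p): sha256_of(p) for p in outputs},
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return manifest
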