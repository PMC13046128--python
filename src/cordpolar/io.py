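"""Reading stored sections and study manifests."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from skimage.draw import polygon2mask

from .detect import MARKERS
from .geometry import roi_centroid
from .imgproc import ChannelStack, SectionGeometry


def load_mask(directory: Path, name: str, shape) -> np.ndarray:
    """Load a binary mask: prefers ``{name}_mask.tif``, else rasterises the
    ``{name}_roi.csv`` polygon (columns x, y in px)."""
    tif = directory / f"{name}_mask.tif"
    if tif.exists():
        return tifffile.imread(tif).astype(bool)
    csv = directory / f"{name}_roi.csv"
    poly = pd.read_csv(csv)
    return polygon2mask(shape, np.column_stack([poly["y"], poly["x"]]))


def load_section_dir(directory, pixel_size: float,
                     dorsal_up: bool = True):
    """Load one section directory: per-marker TIFF stacks + gray/canal ROIs.

    Returns ``(stacks, geometry)`` as consumed by the analysis pipeline.
    """
    directory = Path(directory)
    stacks = {}
    for marker in MARKERS:
        path = directory / f"{marker}.tif"
        if not path.exists():
            raise FileNotFoundError(path)
        voxels = tifffile.imread(path)
        if voxels.ndim == 2:
            voxels = voxels[None]
        stacks[marker] = ChannelStack(voxels, pixel_size, marker)
    shape = next(iter(stacks.values())).shape
    gray = load_mask(directory, "gray", shape)
    canal = load_mask(directory, "canal", shape)
    geometry = SectionGeometry(gray, canal, roi_centroid(canal), dorsal_up)
    return stacks, geometry


def read_manifest(path) -> pd.DataFrame:
    """Read a study manifest CSV; directories resolve relative to it."""
    path = Path(path)
    manifest = pd.read_csv(path)
    required = {"section_id", "animal", "genotype", "lumbar_level", "directory"}
    missing = required - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    manifest["directory"] = [str((path.parent / d)) for d in
                             manifest["directory"]]
    return manifest
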