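"""Dataset container and readers/writers.

A dataset is a float64 image stack in [0, 1] plus a tabular manifest with
one row per slice record:

    subject_id, class, scanner_id, slice_idx, volume_idx,
    slice_thickness_mm, pixel_spacing_x_mm, pixel_spacing_y_mm, path

Images travel as 8-bit grayscale PNG on disk and as floats in memory.
An optional ``frames`` array (N, T, H, W) carries the temporal axis for
the ConvGRU path; 4-D NIfTI volumes can be expanded into slice records.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from PIL import Image

MANIFEST_COLUMNS = [
    "subject_id", "class", "scanner_id", "slice_idx", "volume_idx",
    "slice_thickness_mm", "pixel_spacing_x_mm", "pixel_spacing_y_mm", "path",
]

__all__ = ["SliceDataset", "load_dataset", "load_nifti_volume", "MANIFEST_COLUMNS"]


@dataclass
class SliceDataset:
    images: np.ndarray                  # (N, H, W) float64 in [0, 1]
    manifest: pd.DataFrame              # N rows, MANIFEST_COLUMNS schema
    frames: np.ndarray | None = None    # optional (N, T, H, W)

    def __post_init__(self):
        if len(self.images) != len(self.manifest):
            raise ValueError("images and manifest row counts differ")

    def __len__(self):
        return len(self.manifest)

    @property
    def labels(self) -> np.ndarray:
        return self.manifest["class"].to_numpy(dtype=np.intp)

    @property
    def subjects(self) -> np.ndarray:
        return self.manifest["subject_id"].to_numpy()

    @property
    def scanners(self) -> np.ndarray:
        return self.manifest["scanner_id"].to_numpy()

    def take(self, index) -> "SliceDataset":
        index = np.asarray(index)
        return SliceDataset(
            self.images[index],
            self.manifest.iloc[index].reset_index(drop=True),
            None if self.frames is None else self.frames[index],
        )

    def save(self, out_dir: str) -> str:
        """Write PNG slices plus ``manifest.csv``; returns the manifest path."""
        img_dir = os.path.join(out_dir, "images")
        os.makedirs(img_dir, exist_ok=True)
        manifest = self.manifest.copy()
        paths = []
        for i in range(len(self)):
            row = manifest.iloc[i]
            name = (f"s{row['subject_id']}_sl{int(row['slice_idx'])}"
                    f"_v{int(row['volume_idx'])}.png")
            arr = np.clip(self.images[i] * 255.0, 0, 255).astype(np.uint8)
            Image.fromarray(arr, mode="L").save(os.path.join(img_dir, name))
            paths.append(os.path.join("images", name))
        manifest["path"] = paths
        mpath = os.path.join(out_dir, "manifest.csv")
        manifest.to_csv(mpath, index=False)
        return mpath


def load_dataset(manifest_path: str) -> SliceDataset:
    """Load a PNG slice dataset from its manifest.

    Rejects missing columns, missing files, inconsistent image shapes, and
    duplicate (subject, slice, volume) keys — each with the offending rows.
    """
    manifest = pd.read_csv(manifest_path)
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise ValueError(f"manifest lacks columns {missing}")
    keys = manifest[["subject_id", "slice_idx", "volume_idx"]]
    dup = keys.duplicated()
    if dup.any():
        raise ValueError(f"duplicate (subject, slice, volume) keys at rows "
                         f"{np.flatnonzero(dup).tolist()}")
    base = os.path.dirname(os.path.abspath(manifest_path))
    images, shape = [], None
    for i, rel in enumerate(manifest["path"]):
        path = os.path.join(base, rel)
        if not os.path.exists(path):
            raise FileNotFoundError(f"row {i}: image file missing: {rel}")
        arr = np.asarray(Image.open(path).convert("L"), dtype=np.float64) / 255.0
        if shape is None:
            shape = arr.shape
        elif arr.shape != shape:
            raise ValueError(f"row {i}: image shape {arr.shape} != {shape}")
        images.append(arr)
    return SliceDataset(np.stack(images), manifest)


def load_nifti_volume(path: str, subject_id: str, label: int, scanner_id: str,
                      slice_thickness_mm: float = np.nan,
                      pixel_spacing_mm: tuple = (np.nan, np.nan)) -> SliceDataset:
    """Expand a 4-D NIfTI volume (X, Y, Z, T) into T x Z slice records.

    Voxel metadata is read from the NIfTI header zooms when not given.
    """
    import nibabel as nib

    img = nib.load(path)
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim == 3:
        data = data[..., None]
    if data.ndim != 4:
        raise ValueError(f"expected 3-D/4-D NIfTI, got ndim={data.ndim}")
    zooms = img.header.get_zooms()
    px = pixel_spacing_mm[0] if np.isfinite(pixel_spacing_mm[0]) else float(zooms[0])
    py = pixel_spacing_mm[1] if np.isfinite(pixel_spacing_mm[1]) else float(zooms[1])
    thick = slice_thickness_mm if np.isfinite(slice_thickness_mm) else float(zooms[2])
    lo, hi = data.min(), data.max()
    scale = (hi - lo) if hi > lo else 1.0
    rows, images = [], []
    for t in range(data.shape[3]):
        for z in range(data.shape[2]):
            images.append((data[:, :, z, t].T - lo) / scale)
            rows.append(dict(subject_id=subject_id, **{"class": label},
                             scanner_id=scanner_id, slice_idx=z, volume_idx=t,
                             slice_thickness_mm=thick, pixel_spacing_x_mm=px,
                             pixel_spacing_y_mm=py, path=""))
    return SliceDataset(np.stack(images), pd.DataFrame(rows))
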