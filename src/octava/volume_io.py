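"""Volume containers, readers/writers, surface detection, and flattening.

OCT volumes are stored depth-first: ``intensity[depth, x, y]``. An A-line is
one depth column ``intensity[:, x, y]``; a B-scan is the ``(depth, x)`` slice
at fixed ``y``. Depth index 0 is the shallowest pixel. Before patches are
extracted the tissue surface is detected per A-line and each A-line is
shifted (integer shift, no interpolation) so the surface sits at depth 0.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from enum import IntEnum
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage
from skimage.filters import threshold_otsu

logger = logging.getLogger(__name__)

BACKGROUND_SURFACE = -1


class Label(IntEnum):
    """Per-A-line tissue class."""

    BACKGROUND = 0
    LA = 1
    TRANSITION = 2
    PV = 3


@dataclass
class LabelMap:
    """Per-A-line class annotation on the volume's (x, y) grid."""

    label: np.ndarray  # (nx, ny) int array of Label values

    def __post_init__(self) -> None:
        self.label = np.asarray(self.label, dtype=np.int8)
        if self.label.ndim != 2:
            raise ValueError("label map must be 2-D (nx, ny)")

    @property
    def shape(self) -> tuple[int, int]:
        return self.label.shape

    def counts(self) -> dict[str, int]:
        return {lab.name: int(np.sum(self.label == lab)) for lab in Label}


@dataclass
class OCTVolume:
    """A 3-D OCT intensity volume with physical spacing metadata.

    ``domain_tag`` records whether ``intensity`` is linear backscatter or an
    8-bit log-compressed display volume; attenuation estimation requires the
    linear domain.
    """

    intensity: np.ndarray  # (depth, nx, ny)
    axial_spacing: float  # mm / pixel
    lateral_spacing_x: float  # mm / pixel
    lateral_spacing_y: float  # mm / pixel
    junction_id: str
    domain_tag: str = "linear"  # {"linear", "log8bit"}

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity)
        if self.intensity.ndim != 3:
            raise ValueError("intensity must be 3-D (depth, x, y)")
        if min(self.axial_spacing, self.lateral_spacing_x, self.lateral_spacing_y) <= 0:
            raise ValueError("pixel spacings must be strictly positive")
        if self.intensity.size and self.intensity.min() < 0:
            raise ValueError("intensity must be non-negative")
        if not self.junction_id:
            raise ValueError("junction_id must be non-empty (grouping key for CV)")
        if self.domain_tag not in ("linear", "log8bit"):
            raise ValueError(f"unknown domain_tag {self.domain_tag!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensity.shape


def detect_surface(
    volume: OCTVolume,
    *,
    axial_median: int = 5,
    lateral_median: int = 7,
    threshold: float | None = None,
) -> np.ndarray:
    """Locate the tissue surface depth (pixels) for every A-line.

    Intensities are smoothed with an axial median filter, thresholded (Otsu
    per B-scan unless an explicit threshold is given) and the shallowest
    supra-threshold depth is taken; the resulting surface track is smoothed
    with a lateral median filter. A-lines that never exceed the threshold are
    marked ``BACKGROUND_SURFACE`` (-1).
    """
    depth, nx, ny = volume.shape
    if volume.intensity.size == 0:
        raise ValueError("empty volume")
    inten = volume.intensity.astype(np.float32, copy=False)
    smoothed = ndimage.median_filter(inten, size=(axial_median, 1, 1), mode="nearest")

    surface = np.full((nx, ny), BACKGROUND_SURFACE, dtype=np.int64)
    for y in range(ny):
        bscan = smoothed[:, :, y]
        if threshold is None:
            lo, hi = float(bscan.min()), float(bscan.max())
            if hi <= lo:  # constant B-scan: nothing to segment
                continue
            thr = threshold_otsu(bscan)
        else:
            thr = threshold
        above = bscan >= thr
        has_tissue = above.any(axis=0)
        first = np.argmax(above, axis=0)
        col = np.where(has_tissue, first, BACKGROUND_SURFACE)
        if has_tissue.any() and lateral_median > 1:
            sm = ndimage.median_filter(col.astype(np.float64), size=lateral_median, mode="nearest")
            col = np.where(has_tissue, np.rint(sm).astype(np.int64), BACKGROUND_SURFACE)
        surface[:, y] = col

    if not (surface >= 0).any():
        logger.warning("no tissue found in volume %s: all A-lines background", volume.junction_id)
    return surface


def flatten(volume: OCTVolume, surface: np.ndarray) -> OCTVolume:
    """Shift each A-line up so the detected surface sits at depth 0.

    Integer shifts only, so 8-bit values survive intact; vacated deep pixels
    are zero-filled. Background A-lines (surface == -1) are left unshifted.
    Idempotent: a flat surface at 0 produces a zero shift.
    """
    depth, nx, ny = volume.shape
    surface = np.asarray(surface)
    if surface.shape != (nx, ny):
        raise ValueError("surface grid does not match volume grid")
    if surface.max(initial=BACKGROUND_SURFACE) >= depth:
        raise ValueError("surface deeper than volume")

    shift = np.where(surface >= 0, surface, 0)
    # gather: out[i] = in[i + shift], zero beyond the bottom
    idx = np.arange(depth)[:, None, None] + shift[None, :, :]
    valid = idx < depth
    idx = np.minimum(idx, depth - 1)
    out = np.take_along_axis(volume.intensity, idx, axis=0)
    out = np.where(valid, out, 0).astype(volume.intensity.dtype, copy=False)
    return replace(volume, intensity=out)


# ---------------------------------------------------------------------------
# container I/O


def write_hdf5(path: str | Path, volume: OCTVolume, labels: LabelMap | None = None,
               extra_attrs: dict | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("intensity", data=volume.intensity)
        if labels is not None:
            f.create_dataset("labels", data=labels.label)
        f.attrs["axial_spacing"] = volume.axial_spacing
        f.attrs["lateral_spacing_x"] = volume.lateral_spacing_x
        f.attrs["lateral_spacing_y"] = volume.lateral_spacing_y
        f.attrs["junction_id"] = volume.junction_id
        f.attrs["domain_tag"] = volume.domain_tag
        for k, v in (extra_attrs or {}).items():
            f.attrs[k] = v


def read_hdf5(path: str | Path) -> tuple[OCTVolume, LabelMap | None]:
    with h5py.File(path, "r") as f:
        vol = OCTVolume(
            intensity=f["intensity"][...],
            axial_spacing=float(f.attrs["axial_spacing"]),
            lateral_spacing_x=float(f.attrs["lateral_spacing_x"]),
            lateral_spacing_y=float(f.attrs["lateral_spacing_y"]),
            junction_id=str(f.attrs["junction_id"]),
            domain_tag=str(f.attrs["domain_tag"]),
        )
        labels = LabelMap(f["labels"][...]) if "labels" in f else None
    return vol, labels


def write_tiff(path: str | Path, volume: OCTVolume) -> None:
    """Write one TIFF page per B-scan (depth x nx image at each y)."""
    pages = np.moveaxis(volume.intensity, 2, 0)  # (ny, depth, nx)
    meta = {
        "axial_spacing": volume.axial_spacing,
        "lateral_spacing_x": volume.lateral_spacing_x,
        "lateral_spacing_y": volume.lateral_spacing_y,
        "junction_id": volume.junction_id,
        "domain_tag": volume.domain_tag,
    }
    tifffile.imwrite(path, pages, description=json.dumps(meta))


def read_tiff(path: str | Path) -> OCTVolume:
    with tifffile.TiffFile(path) as tf:
        pages = tf.asarray()
        meta = json.loads(tf.pages[0].description)
    return OCTVolume(
        intensity=np.moveaxis(pages, 0, 2),
        axial_spacing=float(meta["axial_spacing"]),
        lateral_spacing_x=float(meta["lateral_spacing_x"]),
        lateral_spacing_y=float(meta["lateral_spacing_y"]),
        junction_id=str(meta["junction_id"]),
        domain_tag=str(meta["domain_tag"]),
    )


def write_labels_csv(path: str | Path, labels: LabelMap) -> None:
    nx, ny = labels.shape
    xs, ys = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    pd.DataFrame({
        "x": xs.ravel(),
        "y": ys.ravel(),
        "label": [Label(v).name for v in labels.label.ravel()],
    }).to_csv(path, index=False)


def read_labels_csv(path: str | Path) -> LabelMap:
    df = pd.read_csv(path)
    nx, ny = df["x"].max() + 1, df["y"].max() + 1
    arr = np.zeros((nx, ny), dtype=np.int8)
    arr[df["x"].to_numpy(), df["y"].to_numpy()] = [Label[n] for n in df["label"]]
    return LabelMap(arr)
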