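"""Tile flattened volumes into fixed-size patches and apply QC criteria.

Patches are 64 px deep x 128 px wide by default (235 um x 800 um at the
default spacings), taken from the top 64 rows of a flattened B-scan on a
non-overlapping grid anchored at x = 0; partial edge tiles are discarded.

A candidate patch is accepted only if

1. at least 90% of its pixels have intensity greater than zero,
2. all A-lines within it carry the same label, and that label is LA or PV
   (transition tissue mixes both classes and is excluded), and
3. no A-line in the patch is entirely zero.

"No 0 intensity A-lines" is read as "no A-line whose pixels are ALL zero";
an A-line with some zero pixels can still pass provided criterion 1 holds
(a literal all-pixels-nonzero reading would make criterion 1 redundant).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .volume_io import Label, LabelMap, OCTVolume

DEFAULT_PATCH_SHAPE = (64, 128)  # (depth_px, width_px)
#: alternative shapes from the patch-size sweep, px (depth, width)
PATCH_SHAPE_CHOICES = ((32, 32), (32, 128), (64, 32), (64, 128))

MIN_NONZERO_FRACTION = 0.90


@dataclass
class Patch:
    """One image tile with its provenance.

    ``pixels`` is the 8-bit display tile used for texture/statistical
    features and as CNN input; ``linear`` is the same tile in the linear
    intensity domain, required for attenuation estimation.
    """

    pixels: np.ndarray  # (depth_px, width_px) uint8
    linear: np.ndarray | None  # (depth_px, width_px) float, or None
    aline_labels: np.ndarray  # (width_px,) per-A-line labels
    label: int  # Label value; for candidates, the consensus-or-first label
    junction_id: str
    grid_x: int
    grid_y: int
    axial_spacing: float
    lateral_spacing_x: float

    @property
    def physical_size_mm(self) -> tuple[float, float]:
        d, w = self.pixels.shape
        return (d * self.axial_spacing, w * self.lateral_spacing_x)


def tile(
    volume: OCTVolume,
    labels: LabelMap,
    patch_shape: tuple[int, int] = DEFAULT_PATCH_SHAPE,
    linear_volume: OCTVolume | None = None,
) -> list[Patch]:
    """Cut candidate patches from a flattened volume.

    Only the top ``depth_px`` rows are considered (deep signal is dominated
    by roll-off); the lateral grid is non-overlapping, anchored at x = 0,
    one row of tiles per B-scan. Candidates still carry mixed labels —
    :func:`qc_filter` decides acceptance.
    """
    depth_px, width_px = patch_shape
    depth, nx, ny = volume.shape
    if labels.shape != (nx, ny):
        raise ValueError("label grid does not match volume grid")
    if depth_px > depth:
        raise ValueError("patch deeper than volume")
    # a narrower-than-patch grid simply yields no complete tiles
    if linear_volume is not None and linear_volume.shape != volume.shape:
        raise ValueError("linear volume shape mismatch")

    n_tiles_x = nx // width_px
    out: list[Patch] = []
    for y in range(ny):
        for tx in range(n_tiles_x):
            x0 = tx * width_px
            pix = volume.intensity[:depth_px, x0:x0 + width_px, y]
            lin = (linear_volume.intensity[:depth_px, x0:x0 + width_px, y]
                   if linear_volume is not None else None)
            lab = labels.label[x0:x0 + width_px, y]
            out.append(Patch(
                pixels=np.ascontiguousarray(pix),
                linear=np.ascontiguousarray(lin) if lin is not None else None,
                aline_labels=lab.copy(),
                label=int(lab[0]),
                junction_id=volume.junction_id,
                grid_x=tx,
                grid_y=y,
                axial_spacing=volume.axial_spacing,
                lateral_spacing_x=volume.lateral_spacing_x,
            ))
    return out


def qc_passes(pixels: np.ndarray, aline_labels: np.ndarray,
              min_nonzero_fraction: float = MIN_NONZERO_FRACTION) -> tuple[bool, str | None]:
    """Apply the three inclusion criteria to one candidate.

    Returns (accepted, rejection_reason). Reasons: ``nonzero_fraction``,
    ``mixed_or_invalid_label``, ``zero_aline``.
    """
    nonzero = pixels > 0
    if nonzero.mean() < min_nonzero_fraction:
        return False, "nonzero_fraction"
    first = aline_labels[0]
    if first not in (Label.LA, Label.PV) or not np.all(aline_labels == first):
        return False, "mixed_or_invalid_label"
    if np.any(~nonzero.any(axis=0)):
        return False, "zero_aline"
    return True, None


def qc_filter(
    candidates: list[Patch],
    min_nonzero_fraction: float = MIN_NONZERO_FRACTION,
) -> tuple[list[Patch], dict[str, int]]:
    """Filter candidates by the three criteria; order-invariant.

    Accepted patches inherit the (single) common A-line label. Returns the
    accepted list and per-criterion rejection counts.
    """
    accepted: list[Patch] = []
    rejects = {"nonzero_fraction": 0, "mixed_or_invalid_label": 0, "zero_aline": 0}
    for p in candidates:
        ok, reason = qc_passes(p.pixels, p.aline_labels, min_nonzero_fraction)
        if ok:
            p.label = int(p.aline_labels[0])
            accepted.append(p)
        else:
            rejects[reason] += 1
    return accepted, rejects


# ---------------------------------------------------------------------------
# patch store


def save_patch_store(path: str | Path, patches: list[Patch],
                     manifest_csv: str | Path | None = None) -> None:
    """Persist patches to HDF5 (+ optional manifest CSV, one row per patch)."""
    if not patches:
        raise ValueError("no patches to save")
    pixels = np.stack([p.pixels for p in patches])
    grid = np.array([[p.grid_x, p.grid_y] for p in patches])
    labels = np.array([p.label for p in patches], dtype=np.int8)
    jids = np.array([p.junction_id for p in patches], dtype=h5py.string_dtype())
    with h5py.File(path, "w") as f:
        f.create_dataset("pixels", data=pixels)
        if patches[0].linear is not None:
            f.create_dataset("linear", data=np.stack([p.linear for p in patches]).astype(np.float32))
        f.create_dataset("label", data=labels)
        f.create_dataset("junction_id", data=jids)
        f.create_dataset("grid_xy", data=grid)
        f.attrs["axial_spacing"] = patches[0].axial_spacing
        f.attrs["lateral_spacing_x"] = patches[0].lateral_spacing_x
    if manifest_csv is not None:
        patch_manifest(patches).to_csv(manifest_csv, index=False)


def load_patch_store(path: str | Path) -> list[Patch]:
    with h5py.File(path, "r") as f:
        pixels = f["pixels"][...]
        linear = f["linear"][...] if "linear" in f else None
        labels = f["label"][...]
        jids = [s.decode() if isinstance(s, bytes) else str(s) for s in f["junction_id"][...]]
        grid = f["grid_xy"][...]
        dz = float(f.attrs["axial_spacing"])
        dx = float(f.attrs["lateral_spacing_x"])
    out = []
    for i in range(len(labels)):
        width = pixels.shape[2]
        out.append(Patch(
            pixels=pixels[i],
            linear=linear[i] if linear is not None else None,
            aline_labels=np.full(width, labels[i], dtype=np.int8),
            label=int(labels[i]),
            junction_id=jids[i],
            grid_x=int(grid[i, 0]),
            grid_y=int(grid[i, 1]),
            axial_spacing=dz,
            lateral_spacing_x=dx,
        ))
    return out


def patch_manifest(patches: list[Patch]) -> pd.DataFrame:
    return pd.DataFrame({
        "junction_id": [p.junction_id for p in patches],
        "grid_x": [p.grid_x for p in patches],
        "grid_y": [p.grid_y for p in patches],
        "label": [Label(p.label).name for p in patches],
        "depth_px": [p.pixels.shape[0] for p in patches],
        "width_px": [p.pixels.shape[1] for p in patches],
    })
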