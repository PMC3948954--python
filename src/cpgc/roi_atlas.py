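"""ROI geometry: coordinate table handling and spherical voxel masks.

The analysis operates on 33 regions of interest drawn from four resting-state
networks — default mode (DMN), hippocampal-cortical memory (HCMN), dorsal
attention (DAN) and fronto-parietal control (FPCN).  Three nodes (PCC and the
two posterior inferior parietal lobules) appear in both DMN and HCMN with
slightly different centers; they are deliberately kept as distinct ROIs, so a
name is only unique together with its network label.

Coordinates are stereotaxic millimetre positions (x negative = left).  ROIs
are closed balls of a given radius (default 12 mm) around the listed peak,
optionally intersected with a brain mask on the voxel grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

NETWORKS = ("DMN", "HCMN", "DAN", "FPCN")

_REQUIRED_COLUMNS = ("name", "network", "x", "y", "z")


class RoiTableError(ValueError):
    """Malformed ROI coordinate table."""


@dataclass(frozen=True)
class RoiSpec:
    """One spherical ROI: label, network membership, center (mm) and radius."""

    name: str
    network: str
    center: tuple[float, float, float]
    radius: float = 12.0

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError(f"ROI {self.name!r}: radius must be > 0")
        if self.network not in NETWORKS:
            raise ValueError(
                f"ROI {self.name!r}: unknown network {self.network!r} "
                f"(expected one of {NETWORKS})")

    @property
    def label(self) -> str:
        """Unique label ``name@network`` used as a column header downstream."""
        return f"{self.name}@{self.network}"


@dataclass
class RoiSet:
    """Ordered ROI collection; the order fixes every downstream matrix index."""

    rois: list[RoiSpec] = field(default_factory=list)

    def __post_init__(self):
        seen = set()
        for r in self.rois:
            key = (r.name, r.network)
            if key in seen:
                raise RoiTableError(f"duplicate ROI name+network pair: {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.rois)

    def __iter__(self):
        return iter(self.rois)

    def __getitem__(self, i: int) -> RoiSpec:
        return self.rois[i]

    @property
    def labels(self) -> list[str]:
        return [r.label for r in self.rois]

    def network_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for r in self.rois:
            counts[r.network] = counts.get(r.network, 0) + 1
        return counts

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "name": [r.name for r in self.rois],
                "network": [r.network for r in self.rois],
                "x": [r.center[0] for r in self.rois],
                "y": [r.center[1] for r in self.rois],
                "z": [r.center[2] for r in self.rois],
                "radius": [r.radius for r in self.rois],
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def load_roi_table(path) -> RoiSet:
    """Load an ROI coordinate TSV (columns name, network, x, y, z[, radius]).

    File order is preserved; duplicate name+network pairs are rejected.
    A missing ``radius`` column defaults every ROI to 12 mm.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise RoiTableError(f"{path}: empty ROI table")
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise RoiTableError(f"{path}: missing required column(s) {missing}")
    if len(df) == 0:
        raise RoiTableError(f"{path}: ROI table has a header but no rows")
    if "radius" not in df.columns:
        df["radius"] = "12"
    rois = []
    for irow, row in df.iterrows():
        try:
            center = (float(row["x"]), float(row["y"]), float(row["z"]))
            radius = float(row["radius"])
        except (TypeError, ValueError):
            raise RoiTableError(
                f"{path}: non-numeric coordinate in row {irow + 1} "
                f"(ROI {row['name']!r})")
        rois.append(RoiSpec(str(row["name"]), str(row["network"]), center, radius))
    return RoiSet(rois)


def default_roi_set() -> RoiSet:
    """The packaged 33-ROI table (12 DMN, 6 HCMN, 6 DAN, 9 FPCN)."""
    with resources.as_file(resources.files("cpgc") / "data" / "roi_table.tsv") as p:
        return load_roi_table(p)


@dataclass
class VoxelMask:
    """Member voxels of one ROI on a voxel grid.

    ``indices`` holds integer (i, j, k) voxel indices; ``affine`` maps voxel
    index to millimetre coordinates of the voxel center.  ``empty`` flags a
    sphere that missed the grid entirely (returned, not raised).
    """

    shape: tuple[int, int, int]
    affine: np.ndarray
    indices: np.ndarray  # (n, 3) int
    name: str = ""

    @property
    def empty(self) -> bool:
        return len(self.indices) == 0

    def __len__(self) -> int:
        return len(self.indices)

    def to_dense(self) -> np.ndarray:
        out = np.zeros(self.shape, dtype=bool)
        if len(self.indices):
            out[tuple(self.indices.T)] = True
        return out

    def centers_mm(self) -> np.ndarray:
        hom = np.c_[self.indices, np.ones(len(self.indices))]
        return (self.affine @ hom.T).T[:, :3]


def build_sphere_mask(roi: RoiSpec,
                      shape: Sequence[int],
                      affine: np.ndarray,
                      brain_mask: np.ndarray | None = None) -> VoxelMask:
    """Voxels whose centers lie within ``roi.radius`` mm of the ROI center.

    Distance is Euclidean on voxel centers with a closed-ball (``<=``)
    convention, intersected with ``brain_mask`` (a dense boolean array on the
    same grid) when given.  An empty result is returned with ``empty=True``
    rather than raised, so callers can warn per ROI.
    """
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise ValueError("affine must be 4x4")
    try:
        inv = np.linalg.inv(affine)
    except np.linalg.LinAlgError:
        raise ValueError("grid affine is not invertible")
    shape = tuple(int(s) for s in shape)
    center = np.asarray(roi.center, dtype=float)

    # bounding box of the sphere in voxel space, from the 8 corners of the
    # mm-space bounding cube (exact for affines with rotation; padded by 1)
    corners = center + roi.radius * np.array(
        [[sx, sy, sz] for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)])
    vox = (inv @ np.c_[corners, np.ones(8)].T).T[:, :3]
    lo = np.maximum(np.floor(vox.min(axis=0)).astype(int) - 1, 0)
    hi = np.minimum(np.ceil(vox.max(axis=0)).astype(int) + 1, np.array(shape) - 1)
    if np.any(lo > hi):
        return VoxelMask(shape, affine, np.empty((0, 3), dtype=int), roi.name)

    grids = np.meshgrid(*[np.arange(l, h + 1) for l, h in zip(lo, hi)],
                        indexing="ij")
    idx = np.stack([g.ravel() for g in grids], axis=1)
    mm = (affine @ np.c_[idx, np.ones(len(idx))].T).T[:, :3]
    inside = np.linalg.norm(mm - center, axis=1) <= roi.radius
    idx = idx[inside]
    if brain_mask is not None:
        brain_mask = np.asarray(brain_mask, dtype=bool)
        if brain_mask.shape != shape:
            raise ValueError("brain mask shape does not match grid shape")
        idx = idx[brain_mask[tuple(idx.T)]]
    return VoxelMask(shape, affine, idx, roi.name)


def build_all_masks(rois: Iterable[RoiSpec], shape, affine,
                    brain_mask: np.ndarray | None = None) -> list[VoxelMask]:
    return [build_sphere_mask(r, shape, affine, brain_mask) for r in rois]


def save_mask_nifti(mask: VoxelMask, path) -> None:
    """Write a mask as a NIfTI volume (optional volumetric interface)."""
    import nibabel as nib

    nib.save(nib.Nifti1Image(mask.to_dense().astype(np.uint8), mask.affine),
             str(Path(path)))
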