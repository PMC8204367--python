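"""Lesion image handling: aligned binary masks, overlap maps, topography.

All images live on a common voxel grid with a shared affine. Masks are kept
as boolean arrays in memory; NIfTI-1 is the on-disk format (via nibabel).
The world-space convention is RAS: negative world x is the left hemisphere.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "LesionImage",
    "LesionCohort",
    "read_mask",
    "write_mask",
    "overlap_map",
    "classify_topography",
    "lesion_volume",
    "resample_nearest",
    "hemisphere_of",
]


@dataclass
class LesionImage:
    """One subject's binary lesion mask on the cohort grid."""

    mask: np.ndarray
    affine: np.ndarray
    subject_id: str

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask)
        if self.mask.ndim != 3:
            raise ValidationError(
                f"lesion mask for {self.subject_id!r} must be 3D, got {self.mask.ndim}D"
            )
        self.mask = self.mask.astype(bool)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValidationError("affine must be 4x4")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass
class LesionCohort:
    """A stack of aligned lesion images plus optional brain mask."""

    images: list[LesionImage]
    brain_mask: np.ndarray | None = None
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not self.images:
            raise ValidationError("cohort must contain at least one lesion image")
        ids = [im.subject_id for im in self.images]
        if len(set(ids)) != len(ids):
            raise ValidationError("subject_ids must be unique within a cohort")
        ref = self.images[0]
        for im in self.images:
            if im.mask.shape != ref.mask.shape:
                raise ValidationError(
                    f"grid mismatch for {im.subject_id!r}: "
                    f"{im.mask.shape} vs {ref.mask.shape}"
                )
            if not np.allclose(im.affine, ref.affine, atol=1e-6):
                raise ValidationError(f"affine mismatch for {im.subject_id!r}")
        if self.affine is None:
            self.affine = ref.affine.copy()

    def __len__(self) -> int:
        return len(self.images)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.images[0].mask.shape

    @property
    def subject_ids(self) -> list[str]:
        return [im.subject_id for im in self.images]

    def stack(self) -> np.ndarray:
        """n_subjects x grid boolean array."""
        return np.stack([im.mask for im in self.images])

    @classmethod
    def from_manifest(cls, manifest_path: str | Path, brain_mask: np.ndarray | None = None) -> "LesionCohort":
        """Load a cohort from a ``subject_id,path`` CSV manifest.

        Relative paths are resolved against the manifest's directory.
        """
        manifest_path = Path(manifest_path)
        table = pd.read_csv(manifest_path)
        if not {"subject_id", "path"} <= set(table.columns):
            raise ValidationError("manifest must have columns subject_id,path")
        images = []
        for _, row in table.iterrows():
            p = Path(row["path"])
            if not p.is_absolute():
                p = manifest_path.parent / p
            images.append(read_mask(p, subject_id=str(row["subject_id"])))
        return cls(images=images, brain_mask=brain_mask)


def read_mask(path: str | Path, subject_id: str | None = None) -> LesionImage:
    """Read a NIfTI lesion mask, binarizing at 0.5 with a warning if needed."""
    path = Path(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data)
    if data.ndim != 3:
        raise ValidationError(f"{path} is not a 3D image (shape {data.shape})")
    near_binary = np.isclose(data, 0, atol=1e-6) | np.isclose(data, 1, atol=1e-6)
    if not near_binary.all():
        warnings.warn(
            f"{path.name}: {int((~near_binary).sum())} non-binary voxels thresholded at 0.5",
            stacklevel=2,
        )
    mask = data > 0.5
    sid = subject_id if subject_id is not None else path.name.split(".")[0]
    if not mask.any():
        warnings.warn(f"{path.name}: empty lesion mask", stacklevel=2)
    return LesionImage(mask=mask, affine=img.affine, subject_id=sid)


def write_mask(data: np.ndarray, affine: np.ndarray, path: str | Path, dtype=np.uint8) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data).astype(dtype), affine), str(path))


def overlap_map(cohort: LesionCohort) -> np.ndarray:
    """Voxelwise percentage of subjects whose lesion covers each voxel."""
    stack = cohort.stack()
    return 100.0 * stack.sum(axis=0) / len(cohort)


def classify_topography(
    lesion: np.ndarray,
    cortical_mask: np.ndarray,
    subcortical_mask: np.ndarray,
    threshold: float = 0.01,
) -> str:
    """Classify a lesion as cortical / subcortical / cortico-subcortical / other.

    A compartment counts as involved when it holds at least ``threshold``
    (default 1%) of the lesion's volume, so single stray voxels do not flip
    the category.
    """
    lesion = np.asarray(lesion, dtype=bool)
    n = lesion.sum()
    if n == 0:
        warnings.warn("empty lesion classified as 'other'", stacklevel=2)
        return "other"
    frac_cort = (lesion & np.asarray(cortical_mask, dtype=bool)).sum() / n
    frac_sub = (lesion & np.asarray(subcortical_mask, dtype=bool)).sum() / n
    in_cort = frac_cort >= threshold
    in_sub = frac_sub >= threshold
    if in_cort and in_sub:
        return "cortico-subcortical"
    if in_cort:
        return "cortical"
    if in_sub:
        return "subcortical"
    return "other"


def lesion_volume(lesion: LesionImage | np.ndarray, voxel_volume_mm3: float | None = None) -> float:
    """Lesion volume in mm^3 (voxel count times voxel volume)."""
    if isinstance(lesion, LesionImage):
        return lesion.n_voxels * lesion.voxel_volume_mm3
    if voxel_volume_mm3 is None:
        raise ValidationError("voxel_volume_mm3 required when passing a bare array")
    return float(np.asarray(lesion, dtype=bool).sum() * voxel_volume_mm3)


def resample_nearest(
    data: np.ndarray,
    src_affine: np.ndarray,
    target_shape: tuple[int, int, int],
    target_affine: np.ndarray,
    order: int = 0,
) -> np.ndarray:
    """Pull back ``data`` onto a target grid through the two affines.

    order=0 (nearest neighbour) keeps binary masks binary and label images
    label images; order=1 (trilinear) is available for continuous maps.
    """
    src_affine = np.asarray(src_affine, dtype=float)
    target_affine = np.asarray(target_affine, dtype=float)
    if abs(np.linalg.det(src_affine)) < 1e-12:
        raise ValidationError("source affine is not invertible")
    # voxel->voxel map: src_ijk = inv(A_src) @ A_tgt @ tgt_ijk
    M = np.linalg.inv(src_affine) @ target_affine
    ii, jj, kk = np.meshgrid(*[np.arange(s) for s in target_shape], indexing="ij")
    tgt = np.stack([ii, jj, kk], axis=0).reshape(3, -1)
    src = M[:3, :3] @ tgt + M[:3, 3:4]
    out = ndimage.map_coordinates(
        np.asarray(data, dtype=float), src, order=order, mode="grid-constant", cval=0.0
    )
    out = out.reshape(target_shape)
    if order == 0 and np.issubdtype(np.asarray(data).dtype, np.integer):
        out = np.rint(out).astype(np.asarray(data).dtype)
    return out


def hemisphere_of(lesion: np.ndarray, affine: np.ndarray) -> str:
    """'left' or 'right' by majority of lesioned voxels' world x sign."""
    coords = np.argwhere(np.asarray(lesion, dtype=bool))
    if coords.size == 0:
        return "none"
    world_x = coords @ affine[:3, :3].T[:, 0] + affine[0, 3]
    return "left" if (world_x < 0).sum() >= (world_x > 0).sum() else "right"


def topography_summary(
    cohort: LesionCohort, cortical_mask: np.ndarray, subcortical_mask: np.ndarray
) -> pd.DataFrame:
    """Per-subject topography class, hemisphere and volume table."""
    rows = []
    for im in cohort.images:
        rows.append(
            {
                "subject_id": im.subject_id,
                "topography": classify_topography(im.mask, cortical_mask, subcortical_mask),
                "hemisphere": hemisphere_of(im.mask, im.affine),
                "volume_mm3": lesion_volume(im),
                "n_voxels": im.n_voxels,
            }
        )
    return pd.DataFrame(rows)
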