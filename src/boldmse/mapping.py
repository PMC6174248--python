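"""Voxelwise MSE maps and spatial summaries (tissue masks, ROI spheres).

A subject's preprocessed 4-D volume becomes an :class:`MseMapStack`: one
3-D sample-entropy map per scale factor, on the input grid, with
non-analyzable or undefined-entropy voxels carried as NaN.  Spheres are
defined in the affine's mm space (voxel-center distance, inclusive
boundary), so peak coordinates reported in standard space can be consumed
directly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

from ._kernels import pair_counts_map
from .entropy import MseParams, coarse_grain
from .preprocess import Bold4D

__all__ = [
    "MseMapStack",
    "RoiSpec",
    "voxelwise_mse",
    "mean_entropy_in_mask",
    "extract_roi_sphere",
    "sphere_mask",
    "save_map_stack",
    "load_map_stack",
]

log = logging.getLogger(__name__)


@dataclass
class MseMapStack:
    """Per-subject 3-D entropy maps, one per scale, on the input grid."""

    maps: dict[int, np.ndarray]
    params: MseParams
    affine: np.ndarray
    subject_id: str = ""
    mask: np.ndarray | None = None  # analyzability mask
    undefined_counts: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {m.shape for m in self.maps.values()}
        if len(shapes) > 1:
            raise ValueError(f"scale maps disagree on grid shape: {shapes}")

    @property
    def scales(self) -> tuple[int, ...]:
        return tuple(sorted(self.maps))

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return next(iter(self.maps.values())).shape


@dataclass(frozen=True)
class RoiSpec:
    """A sphere in mm space: name, (X, Y, Z) center, radius."""

    name: str
    center_mm: tuple[float, float, float]
    radius_mm: float = 8.0

    def __post_init__(self) -> None:
        if not self.radius_mm > 0:
            raise ValueError("radius_mm must be positive")


def voxelwise_mse(
    vol: Bold4D,
    mask: np.ndarray,
    params: MseParams,
    subject_id: str = "",
) -> MseMapStack:
    """Per-voxel MSE curves over a preprocessed volume.

    Voxels outside ``mask`` (or with NaN data) are missing in every scale
    map.  Per-scale counts of in-mask voxels with undefined entropy are
    kept in ``undefined_counts`` and logged.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != vol.spatial_shape:
        raise ValueError(
            f"mask shape {mask.shape} != volume grid {vol.spatial_shape}"
        )
    mat = vol.to_matrix()
    flat_mask = mask.ravel() & np.all(np.isfinite(mat), axis=1)
    series = np.ascontiguousarray(mat[flat_mask])
    n_t = series.shape[1]
    # tolerance referenced to the original (scale-1) series SD
    sds = series.std(axis=1)
    analyzable = sds > 0
    r_abs = params.r * np.where(analyzable, sds, 1.0)
    maps: dict[int, np.ndarray] = {}
    undefined: dict[int, int] = {}
    for scale in params.scales:
        flat = np.full(mat.shape[0], np.nan)
        if n_t // scale > params.m + 1 and series.size:
            cg = _coarse_grain_rows(series, scale)
            se = _sampen_rows(cg, params.m, r_abs)
            se[~analyzable] = np.nan
            flat[flat_mask] = se
            undefined[scale] = int(np.isnan(se).sum() - (~analyzable).sum())
        else:
            undefined[scale] = int(flat_mask.sum())
            log.warning(
                "scale %d rejected: floor(%d/%d) <= m+1", scale, n_t, scale
            )
        maps[scale] = flat.reshape(vol.spatial_shape)
    if any(undefined.values()):
        log.info(
            "subject %s: undefined-entropy voxels per scale: %s",
            subject_id,
            undefined,
        )
    return MseMapStack(
        maps=maps,
        params=params,
        affine=vol.affine,
        subject_id=subject_id,
        mask=mask & ~np.isnan(maps[params.scales[0]]),
        undefined_counts=undefined,
    )


def _coarse_grain_rows(series: np.ndarray, scale: int) -> np.ndarray:
    if scale == 1:
        return series
    n_win = series.shape[1] // scale
    return series[:, : n_win * scale].reshape(-1, n_win, scale).mean(axis=2)


def _sampen_rows(cg: np.ndarray, m: int, r_abs: np.ndarray) -> np.ndarray:
    """Row-wise SE; per-row tolerances handled by rescaling each row."""
    # pair_counts_map takes a single radius, so divide each row by its own
    # tolerance and count at radius 1 (match sets are identical).
    scaled = np.ascontiguousarray(cg / r_abs[:, None])
    a, b = pair_counts_map(scaled, m, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = -np.log(a / b)
    se[(a == 0) | (b == 0)] = np.nan
    return se


def mean_entropy_in_mask(stack: MseMapStack, mask: np.ndarray) -> dict[int, float]:
    """Per-scale mean over in-mask analyzable voxels (NaN if none)."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != stack.spatial_shape:
        raise ValueError("mask grid does not match map grid")
    if not mask.any():
        log.warning("empty mask; returning NaN means")
        return {s: float("nan") for s in stack.scales}
    out = {}
    for scale in stack.scales:
        vals = stack.maps[scale][mask]
        vals = vals[np.isfinite(vals)]
        out[scale] = float(vals.mean()) if vals.size else float("nan")
    return out


def sphere_mask(
    shape: tuple[int, int, int], affine: np.ndarray, roi: RoiSpec
) -> np.ndarray:
    """Boolean mask of voxels whose mm-space centers fall within the
    sphere (Euclidean distance, inclusive boundary)."""
    ii, jj, kk = np.meshgrid(
        np.arange(shape[0]), np.arange(shape[1]), np.arange(shape[2]),
        indexing="ij",
    )
    vox = np.stack([ii, jj, kk, np.ones_like(ii)], axis=-1)
    mm = vox @ np.asarray(affine, dtype=float).T
    d2 = ((mm[..., :3] - np.asarray(roi.center_mm)) ** 2).sum(axis=-1)
    return d2 <= roi.radius_mm**2 + 1e-9


def extract_roi_sphere(stack: MseMapStack, roi: RoiSpec) -> dict[int, float]:
    """Per-scale mean entropy within an 8-mm-style sphere.

    Undefined voxels are excluded from the mean; a sphere that misses the
    grid entirely is an error naming the ROI.
    """
    mask = sphere_mask(stack.spatial_shape, stack.affine, roi)
    if not mask.any():
        raise ValueError(
            f"ROI '{roi.name}' at {roi.center_mm} (r={roi.radius_mm} mm) "
            "contains no voxels on this grid"
        )
    return mean_entropy_in_mask(stack, mask)


def save_map_stack(stack: MseMapStack, out_dir, subject_id: str | None = None):
    """Write one NIfTI per scale as <subject>_m<m>_r<r>_scale<l>.nii.gz."""
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sid = subject_id or stack.subject_id or "subject"
    paths = []
    for scale in stack.scales:
        img = nib.Nifti1Image(
            stack.maps[scale].astype(np.float32), stack.affine
        )
        p = out_dir / f"{sid}_{stack.params.label}_scale{scale}.nii.gz"
        nib.save(img, p)
        paths.append(p)
    return paths


def load_map_stack(paths, params: MseParams, subject_id: str = "") -> MseMapStack:
    """Rebuild a stack from per-scale NIfTI files (scale parsed from name)."""
    maps = {}
    affine = None
    for p in paths:
        img = nib.load(str(p))
        name = str(p)
        scale = int(name.rsplit("scale", 1)[1].split(".")[0])
        maps[scale] = np.asarray(img.dataobj, dtype=np.float64)
        affine = img.affine
    return MseMapStack(
        maps=maps, params=params, affine=affine, subject_id=subject_id
    )
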