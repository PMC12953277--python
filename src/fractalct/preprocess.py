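"""CT volume and tumor-mask ingestion plus geometric preprocessing.

Volumes are held as plain numpy grids with voxel spacing in millimetres.
Conventions used throughout the package:

* voxel indices are 0-based; the physical centre of voxel ``(0, 0, 0)`` is
  at ``origin``;
* crops and box grids use half-open index intervals ``[lo, hi)``;
* resampling to a target spacing ``t`` produces ``round(extent_mm / t)``
  voxels per axis, where ``extent_mm = shape * spacing``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "CTVolume",
    "SegmentationMask",
    "QuantizedVolume",
    "load_volume",
    "load_mask",
    "save_volume",
    "save_mask",
    "resample_isotropic",
    "resample_mask",
    "quantize_intensity",
    "crop_to_roi",
    "largest_component",
    "DEFAULT_HU_WINDOW",
]

DEFAULT_HU_WINDOW = (-200.0, 400.0)


@dataclass
class CTVolume:
    """A 3D scalar field in Hounsfield units on a regular grid."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_order: str = "ijk"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D, got ndim={self.data.ndim}")
        if self.data.size < 1:
            raise ValueError("volume must contain at least one voxel")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive numbers, got {self.spacing}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def extent_mm(self) -> tuple[float, float, float]:
        return tuple(n * s for n, s in zip(self.shape, self.spacing))


@dataclass
class SegmentationMask:
    """A binary label field aligned to a :class:`CTVolume` grid."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError(f"mask must be 3D, got ndim={arr.ndim}")
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError(f"mask values must be in {{0,1}}, got {uniq[:10]}")
        self.data = arr.astype(np.uint8)
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def foreground_count(self) -> int:
        return int(self.data.sum())


@dataclass
class QuantizedVolume:
    """Integer grid in [0, 255] produced by windowed linear quantization."""

    data: np.ndarray
    window: tuple[float, float]
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.min() < 0 or arr.max() > 255:
            raise ValueError("quantized values must lie in [0, 255]")
        self.data = arr.astype(np.uint8)
        lo, hi = self.window
        if not lo < hi:
            raise ValueError(f"window must satisfy hu_min < hu_max, got {self.window}")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def load_volume(path: str | os.PathLike, format: str = "auto") -> CTVolume:
    """Read a CT volume from a NIfTI file or a DICOM series directory.

    ``format`` may be ``"nifti"``, ``"dicom_series"`` or ``"auto"`` (directory
    implies DICOM).  DICOM support requires the optional ``pydicom`` package.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    if format == "auto":
        format = "dicom_series" if path.is_dir() else "nifti"
    if format == "nifti":
        img = nib.load(str(path))
        data = np.asarray(img.get_fdata(), dtype=np.float64)
        if data.ndim != 3:
            raise ValueError(f"{path}: expected a 3D NIfTI volume, got ndim={data.ndim}")
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        origin = tuple(float(v) for v in img.affine[:3, 3])
        return CTVolume(data=data, spacing=spacing, origin=origin)
    if format == "dicom_series":
        return _load_dicom_series(path)
    raise ValueError(f"unknown format {format!r}")


def _load_dicom_series(dirpath: Path) -> CTVolume:
    try:
        import pydicom
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "reading DICOM series requires the optional 'pydicom' package"
        ) from exc
    files = sorted(p for p in dirpath.iterdir() if p.is_file())
    if not files:
        raise FileNotFoundError(f"no files in DICOM directory {dirpath}")
    slices = [pydicom.dcmread(str(f)) for f in files]
    orient = np.array(slices[0].ImageOrientationPatient, dtype=float)
    normal = np.cross(orient[:3], orient[3:])
    positions = [float(np.dot(normal, np.array(s.ImagePositionPatient, float))) for s in slices]
    order = np.argsort(positions)
    slices = [slices[i] for i in order]
    positions = [positions[i] for i in order]
    gaps = np.diff(positions)
    if len(gaps) and (gaps.max() - gaps.min()) > 1e-3 * max(abs(gaps.mean()), 1e-9):
        raise ValueError(f"inconsistent DICOM slice spacing in {dirpath}: {sorted(set(np.round(gaps, 4)))}")
    dz = float(abs(gaps.mean())) if len(gaps) else 1.0
    dy, dx = (float(v) for v in slices[0].PixelSpacing)
    arrays = []
    for s in slices:
        a = s.pixel_array.astype(np.float64)
        slope = float(getattr(s, "RescaleSlope", 1.0))
        inter = float(getattr(s, "RescaleIntercept", 0.0))
        arrays.append(a * slope + inter)
    data = np.stack(arrays, axis=-1)  # (row, col, slice)
    origin = tuple(float(v) for v in slices[0].ImagePositionPatient)
    return CTVolume(data=data, spacing=(dy, dx, dz), origin=origin)


def load_mask(path: str | os.PathLike) -> SegmentationMask:
    """Read a binary mask from NIfTI; any value > 0.5 becomes foreground."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such mask: {path}")
    img = nib.load(str(path))
    data = (np.asarray(img.get_fdata()) > 0.5).astype(np.uint8)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return SegmentationMask(data=data, spacing=spacing, origin=origin)


def _affine(spacing, origin) -> np.ndarray:
    aff = np.diag([*spacing, 1.0])
    aff[:3, 3] = origin
    return aff


def save_volume(vol: CTVolume, path: str | os.PathLike) -> None:
    nib.save(nib.Nifti1Image(vol.data, _affine(vol.spacing, vol.origin)), str(path))


def save_mask(mask: SegmentationMask, path: str | os.PathLike) -> None:
    nib.save(
        nib.Nifti1Image(mask.data.astype(np.uint8), _affine(mask.spacing, mask.origin)),
        str(path),
    )


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------


def _output_shape(shape, spacing, target: float) -> tuple[int, ...]:
    out = []
    for n, s in zip(shape, spacing):
        if n == 1 and abs(s - target) > 1e-12:
            raise ValueError(
                "cannot resample an axis with a single voxel (undefined extent)"
            )
        out.append(max(1, int(round(n * s / target))))
    return tuple(out)


def _resample_grid(data: np.ndarray, spacing, target: float, order: int) -> np.ndarray:
    out_shape = _output_shape(data.shape, spacing, target)
    axes = [np.arange(n_out) * target / s for n_out, s in zip(out_shape, spacing)]
    grid = np.meshgrid(*axes, indexing="ij")
    coords = np.stack([g.ravel() for g in grid])
    out = ndimage.map_coordinates(data, coords, order=order, mode="nearest")
    return out.reshape(out_shape)


def resample_isotropic(
    vol: CTVolume, target_spacing: float = 1.0, interpolation: str = "linear"
) -> CTVolume:
    """Resample to an isotropic grid by trilinear interpolation."""
    if target_spacing <= 0:
        raise ValueError("target_spacing must be positive")
    if interpolation != "linear":
        raise ValueError(f"unsupported interpolation {interpolation!r}")
    out = _resample_grid(vol.data, vol.spacing, float(target_spacing), order=1)
    return CTVolume(
        data=out,
        spacing=(target_spacing,) * 3,
        origin=vol.origin,
        axis_order=vol.axis_order,
    )


def resample_mask(
    mask: SegmentationMask, target: "float | CTVolume" = 1.0
) -> SegmentationMask:
    """Nearest-neighbour resample of a binary mask.

    ``target`` is either an isotropic spacing in mm, or a :class:`CTVolume`
    whose grid geometry the mask should be brought onto (the physical extents
    must agree within one voxel).
    """
    if isinstance(target, CTVolume):
        for a, (em, ev) in enumerate(zip(_extent(mask), target.extent_mm())):
            if abs(em - ev) > max(mask.spacing[a], target.spacing[a]):
                raise ValueError(
                    f"mask extent {em:.2f} mm does not match target extent {ev:.2f} mm on axis {a}"
                )
        axes = [
            np.arange(n_out) * ts / s
            for n_out, ts, s in zip(target.shape, target.spacing, mask.spacing)
        ]
        grid = np.meshgrid(*axes, indexing="ij")
        coords = np.stack([g.ravel() for g in grid])
        out = ndimage.map_coordinates(mask.data, coords, order=0, mode="nearest")
        out = out.reshape(target.shape)
        return SegmentationMask(data=out, spacing=target.spacing, origin=target.origin)
    t = float(target)
    if t <= 0:
        raise ValueError("target spacing must be positive")
    out = _resample_grid(mask.data, mask.spacing, t, order=0)
    return SegmentationMask(data=out, spacing=(t,) * 3, origin=mask.origin)


def _extent(mask: SegmentationMask) -> tuple[float, ...]:
    return tuple(n * s for n, s in zip(mask.shape, mask.spacing))


# ---------------------------------------------------------------------------
# Intensity quantization
# ---------------------------------------------------------------------------


def quantize_intensity(
    vol: CTVolume, window: tuple[float, float] = DEFAULT_HU_WINDOW
) -> QuantizedVolume:
    """Clip to an HU window and map linearly onto the integers 0..255.

    The mapping is ``floor(255 * (v - lo) / (hi - lo) + 0.5)`` after clipping,
    so window endpoints land exactly on 0 and 255 and the map is monotone.
    """
    lo, hi = (float(window[0]), float(window[1]))
    if not lo < hi:
        raise ValueError(f"window must satisfy hu_min < hu_max, got {window}")
    if not np.all(np.isfinite(vol.data)):
        raise ValueError("volume contains non-finite values")
    clipped = np.clip(vol.data, lo, hi)
    q = np.floor(255.0 * (clipped - lo) / (hi - lo) + 0.5).astype(np.uint8)
    return QuantizedVolume(data=q, window=(lo, hi), spacing=vol.spacing, origin=vol.origin)


# ---------------------------------------------------------------------------
# Cropping and component selection
# ---------------------------------------------------------------------------


def foreground_bbox(mask_data: np.ndarray) -> tuple[tuple[int, int], ...]:
    """Half-open bounding box ``((lo, hi), ...)`` of the foreground voxels."""
    if not mask_data.any():
        raise ValueError("mask has no foreground voxels")
    bounds = []
    for axis in range(mask_data.ndim):
        other = tuple(a for a in range(mask_data.ndim) if a != axis)
        prof = mask_data.any(axis=other)
        idx = np.nonzero(prof)[0]
        bounds.append((int(idx[0]), int(idx[-1]) + 1))
    return tuple(bounds)


def crop_to_roi(
    vol: CTVolume, mask: SegmentationMask, margin_voxels: int = 0
) -> tuple[CTVolume, SegmentationMask]:
    """Crop volume and mask to the foreground bounding box plus a margin."""
    if margin_voxels < 0:
        raise ValueError("margin_voxels must be >= 0")
    if vol.shape != mask.shape:
        raise ValueError(f"volume shape {vol.shape} != mask shape {mask.shape}")
    bbox = foreground_bbox(mask.data)
    sl = tuple(
        slice(max(0, lo - margin_voxels), min(n, hi + margin_voxels))
        for (lo, hi), n in zip(bbox, vol.shape)
    )
    offset = tuple(s.start for s in sl)
    new_origin = tuple(o + off * sp for o, off, sp in zip(vol.origin, offset, vol.spacing))
    cvol = CTVolume(
        data=vol.data[sl], spacing=vol.spacing, origin=new_origin, axis_order=vol.axis_order
    )
    cmask = SegmentationMask(data=mask.data[sl], spacing=mask.spacing, origin=new_origin)
    return cvol, cmask


def largest_component(mask: SegmentationMask) -> SegmentationMask:
    """Keep the largest 26-connected foreground component.

    Ties in voxel count are broken by the lexicographically smallest
    bounding-box origin, so the choice is deterministic.
    """
    structure = np.ones((3, 3, 3), dtype=bool)
    labels, n = ndimage.label(mask.data, structure=structure)
    if n == 0:
        raise ValueError("mask has no foreground voxels")
    if n == 1:
        return mask
    counts = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    best = None
    for lab in range(1, n + 1):
        if counts[lab - 1] < counts.max():
            continue
        origin = tuple(int(v.min()) for v in np.nonzero(labels == lab))
        if best is None or origin < best[0]:
            best = (origin, lab)
    keep = (labels == best[1]).astype(np.uint8)
    return SegmentationMask(data=keep, spacing=mask.spacing, origin=mask.origin)
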