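"""NIfTI I/O and ROI-locator preprocessing.

The preprocessing contract mirrors a template-registration ROI extractor:
a template (with a paired atlas of left/right hippocampus labels) is
registered to the native scan, atlas ROI voxels are mapped through the
recovered transform into native space, and per side an axis-aligned
bounding box with a safety margin (default 16 voxels) is cropped,
Z-normalized and zero-padded to dimensions that are multiples of 8.

Conventions: voxel indices are 0-based; boxes are half-open [lo, hi);
world coordinates follow the NIfTI affine (RAS+).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage, optimize
from scipy.spatial.transform import Rotation

__all__ = [
    "Volume",
    "LabelMap",
    "BoundingBox",
    "RoiConfig",
    "AffineTransform",
    "PadRecord",
    "RoiCrop",
    "RegistrationError",
    "read_volume",
    "read_labelmap",
    "write_volume",
    "write_labelmap",
    "register_affine",
    "locate_roi",
    "z_normalize",
    "pad_to_multiple",
    "crop_to_box",
    "unpad",
    "extract_rois",
]


# ---------------------------------------------------------------------------
# domain types


@dataclass
class Volume:
    """A 3D scalar image with a voxel-to-world affine."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D volume, got {self.data.ndim}D")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")

    @property
    def spacing(self):
        """mm per voxel along each axis (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def shape(self):
        return self.data.shape


@dataclass
class LabelMap:
    """An integer segmentation aligned to a Volume grid."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    schema: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D label map, got {self.data.ndim}D")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("label map must be integer-typed")
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def shape(self):
        return self.data.shape


@dataclass
class BoundingBox:
    """Half-open voxel box [lo, hi) per axis."""

    lo: np.ndarray
    hi: np.ndarray

    def __post_init__(self):
        self.lo = np.asarray(self.lo, dtype=int)
        self.hi = np.asarray(self.hi, dtype=int)
        if np.any(self.lo >= self.hi):
            raise ValueError(f"degenerate box: lo={self.lo} hi={self.hi}")

    def slices(self):
        return tuple(slice(int(a), int(b)) for a, b in zip(self.lo, self.hi))

    def clamped(self, shape):
        return BoundingBox(np.maximum(self.lo, 0), np.minimum(self.hi, shape))

    def contains_points(self, pts):
        pts = np.asarray(pts)
        return np.all((pts >= self.lo) & (pts < self.hi), axis=1)

    @property
    def shape(self):
        return tuple(int(b - a) for a, b in zip(self.lo, self.hi))

    def to_dict(self):
        return {"lo": self.lo.tolist(), "hi": self.hi.tolist()}


@dataclass
class RoiConfig:
    margin: int = 16            # safety margin, voxels on every side
    pad_multiple: int = 8       # output dims padded to a multiple of this
    registration_kind: str = "affine"   # 'rigid' | 'affine'
    mirror_right: bool = False  # mirror the right crop to left chirality

    def __post_init__(self):
        if self.margin < 0:
            raise ValueError("margin must be >= 0")
        if self.pad_multiple < 1:
            raise ValueError("pad_multiple must be >= 1")
        if self.registration_kind not in ("rigid", "affine"):
            raise ValueError(f"unknown registration kind {self.registration_kind!r}")


class AffineTransform:
    """Voxel-space affine mapping template coordinates to target coordinates."""

    def __init__(self, matrix):
        self.matrix = np.asarray(matrix, dtype=float)
        if self.matrix.shape != (4, 4):
            raise ValueError("transform matrix must be 4x4")

    @classmethod
    def identity(cls):
        return cls(np.eye(4))

    @classmethod
    def from_translation(cls, t):
        m = np.eye(4)
        m[:3, 3] = t
        return cls(m)

    def apply_points(self, pts):
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        return pts @ self.matrix[:3, :3].T + self.matrix[:3, 3]

    @property
    def inverse(self):
        return AffineTransform(np.linalg.inv(self.matrix))

    @property
    def translation(self):
        return self.matrix[:3, 3]

    def to_dict(self):
        return {"matrix": self.matrix.tolist()}


@dataclass
class PadRecord:
    """Pad widths (before, after) per axis, for exact inverse cropping."""

    before: tuple
    after: tuple

    def inverse_slices(self, shape):
        return tuple(slice(b, s - a) for b, a, s in zip(self.before, self.after, shape))


@dataclass
class RoiCrop:
    """A preprocessed (cropped, normalized, padded) hippocampus subvolume."""

    side: str
    data: np.ndarray
    box: BoundingBox
    pad: PadRecord
    affine: np.ndarray


# ---------------------------------------------------------------------------
# I/O


def _check_3d(img, path):
    shape = img.shape
    if len(shape) == 4 and shape[3] == 1:
        return
    if len(shape) != 3:
        raise ValueError(f"{path}: expected 3D image, got shape {shape}")


def read_volume(path) -> Volume:
    img = nib.load(str(path))
    _check_3d(img, path)
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim == 4:
        data = data[..., 0]
    return Volume(data=data, affine=np.asarray(img.affine))


def read_labelmap(path) -> LabelMap:
    img = nib.load(str(path))
    _check_3d(img, path)
    data = np.asarray(img.dataobj)
    if data.ndim == 4:
        data = data[..., 0]
    if not np.issubdtype(data.dtype, np.integer):
        rounded = np.rint(data)
        if not np.allclose(data, rounded, atol=1e-6):
            raise ValueError(f"{path}: non-integer data in label map")
        data = rounded.astype(np.int16)
    return LabelMap(data=data, affine=np.asarray(img.affine))


def write_volume(path, volume: Volume):
    nib.save(nib.Nifti1Image(volume.data.astype(np.float32), volume.affine), str(path))


def write_labelmap(path, labelmap: LabelMap):
    nib.save(nib.Nifti1Image(labelmap.data.astype(np.int16), labelmap.affine), str(path))


# ---------------------------------------------------------------------------
# registration


class RegistrationError(RuntimeError):
    def __init__(self, message, objective):
        super().__init__(f"{message} (final objective {objective:.6g})")
        self.objective = objective


def _params_to_matrix(params, kind, center):
    """(t, rotvec[, log-scale]) -> 4x4 voxel affine fixing `center`."""
    t = params[:3]
    lin = Rotation.from_rotvec(params[3:6]).as_matrix()
    if kind == "affine":
        lin = lin @ np.diag(np.exp(params[6:9]))
    m = np.eye(4)
    m[:3, :3] = lin
    m[:3, 3] = t + center - lin @ center
    return m


def _resample(moving, matrix, out_shape, order=1):
    """Sample `moving` at matrix-mapped coordinates of the output grid."""
    return ndimage.affine_transform(
        moving, matrix[:3, :3], offset=matrix[:3, 3],
        output_shape=tuple(int(s) for s in out_shape),
        order=order, mode="constant", cval=0.0)


def register_affine(template: Volume, target: Volume, kind: str = "affine",
                    levels=(4, 2, 1), maxiter: int = 120) -> AffineTransform:
    """Recover the template->target voxel affine by multi-resolution MSE descent.

    The built-in optimizer (Powell over translation + rotation [+ log-scale])
    is intended for synthetic scenes with a broad mono-modal similarity
    basin; external registration tools can be substituted for real MRI by
    constructing an :class:`AffineTransform` directly.
    """
    if kind not in ("rigid", "affine"):
        raise ValueError(f"unknown registration kind {kind!r}")
    for name, v in (("template", template), ("target", target)):
        if np.ptp(v.data) == 0:
            raise ValueError(f"{name} volume is constant")

    nparams = 6 if kind == "rigid" else 9
    params = np.zeros(nparams)
    center = (np.asarray(template.shape) - 1) / 2.0
    tpl = template.data.astype(np.float64)
    tgt = target.data.astype(np.float64)

    result = None
    for level in levels:
        sigma = max(level / 2.0, 0.5)
        tpl_s = ndimage.gaussian_filter(tpl, sigma)[::level, ::level, ::level]
        tgt_s = ndimage.gaussian_filter(tgt, sigma)
        sub = np.diag([level, level, level, 1.0])

        def objective(p, tpl_s=tpl_s, tgt_s=tgt_s, sub=sub, level=level):
            q = p.copy()
            q[:3] *= level  # translations optimized in coarse-voxel units
            m = _params_to_matrix(q, kind, center) @ sub
            warped = _resample(tgt_s, m, tpl_s.shape)
            return float(np.mean((warped - tpl_s) ** 2))

        p0 = params.copy()
        p0[:3] /= level
        res = optimize.minimize(objective, p0, method="Powell",
                                options={"maxiter": maxiter, "xtol": 1e-4,
                                         "ftol": 1e-9})
        params = res.x.copy()
        params[:3] *= level
        result = res

    if result is None or not np.all(np.isfinite(params)):
        raise RegistrationError("registration failed to converge",
                                float("nan") if result is None else result.fun)
    return AffineTransform(_params_to_matrix(params, kind, center))


# ---------------------------------------------------------------------------
# ROI location and crop preprocessing


def locate_roi(atlas: LabelMap, transform: AffineTransform, roi_labels,
               config: RoiConfig, grid_shape=None):
    """Map atlas ROI voxels into native space and box them with a margin.

    `roi_labels` is a mapping {'left': id-or-ids, 'right': id-or-ids}.
    Returns (box_left, box_right) in the fixed (left, right) order, clamped
    to `grid_shape` (defaults to the atlas grid).
    """
    if grid_shape is None:
        grid_shape = atlas.shape
    boxes = []
    for side in ("left", "right"):
        ids = np.atleast_1d(roi_labels[side])
        mask = np.isin(atlas.data, ids)
        if not mask.any():
            raise ValueError(f"ROI labels {ids.tolist()} for side {side!r} "
                             "not present in atlas")
        pts = np.argwhere(mask)
        mapped = transform.apply_points(pts)
        lo = np.floor(mapped.min(axis=0)).astype(int) - config.margin
        hi = np.floor(mapped.max(axis=0)).astype(int) + 1 + config.margin
        boxes.append(BoundingBox(lo, hi).clamped(grid_shape))
    return tuple(boxes)


def z_normalize(v: Volume) -> Volume:
    data = v.data.astype(np.float64)
    if data.size <= 1:
        raise ValueError("crop must have more than one voxel")
    sd = data.std()
    if sd == 0:
        raise ValueError("degenerate crop: constant intensity")
    return Volume(data=(data - data.mean()) / sd, affine=v.affine)


def pad_to_multiple(v: Volume, m: int):
    """Zero-pad (centered) so every dim is the next multiple of m.

    Returns (padded Volume, PadRecord); the record inverts the padding
    exactly via :func:`unpad`.
    """
    if m < 1:
        raise ValueError("pad multiple must be >= 1")
    shape = np.asarray(v.shape)
    out = (np.ceil(shape / m) * m).astype(int)
    total = out - shape
    before = total // 2
    after = total - before
    padded = np.pad(v.data, list(zip(before, after)))
    new_affine = v.affine.copy()
    new_affine[:3, 3] -= v.affine[:3, :3] @ before
    return (Volume(data=padded, affine=new_affine),
            PadRecord(tuple(int(b) for b in before), tuple(int(a) for a in after)))


def unpad(data: np.ndarray, record: PadRecord) -> np.ndarray:
    return data[record.inverse_slices(data.shape)]


def crop_to_box(v, box: BoundingBox):
    """Crop a Volume or LabelMap to a box, updating the affine origin."""
    sl = box.slices()
    affine = v.affine.copy()
    affine[:3, 3] += v.affine[:3, :3] @ box.lo
    if isinstance(v, LabelMap):
        return LabelMap(data=v.data[sl], affine=affine, schema=dict(v.schema))
    return Volume(data=v.data[sl], affine=affine)


def extract_rois(volume: Volume, template: Volume, atlas: LabelMap,
                 roi_labels, config: RoiConfig,
                 transform: AffineTransform | None = None):
    """Full ROI-locator chain: register, locate, crop, Z-normalize, pad.

    Returns a list of two RoiCrops in (left, right) order.  A precomputed
    transform may be supplied to skip registration.
    """
    if transform is None:
        transform = register_affine(template, volume, kind=config.registration_kind)
    boxes = locate_roi(atlas, transform, roi_labels, config, grid_shape=volume.shape)
    crops = []
    for side, box in zip(("left", "right"), boxes):
        sub = crop_to_box(volume, box)
        sub = z_normalize(sub)
        if side == "right" and config.mirror_right:
            sub = Volume(data=sub.data[::-1].copy(), affine=sub.affine)
        padded, record = pad_to_multiple(sub, config.pad_multiple)
        crops.append(RoiCrop(side=side, data=padded.data, box=box,
                             pad=record, affine=padded.affine))
    return crops
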