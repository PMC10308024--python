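"""Test-time augmentation, ensemble fusion and voxel-wise vote entropy.

Each preprocessed hippocampus crop is randomly augmented into
``n_versions`` copies (default 21) with horizontal flips, affine
(rotation + isotropic scale) and elastic deformations.  Every ensemble
member predicts every version; each predicted label map is mapped back to
native crop space (flips and affines inverted exactly, elastic fields via
the negated-displacement approximation), and the stack of
``E x n_versions`` aligned predictions is fused by a voxel-wise plurality
vote.  Ties are broken toward the lowest class id (deterministic, and
documented here as the tie rule).

The per-voxel uncertainty is the Shannon entropy of the vote frequencies,

    H(Y | X) = -sum_m p_m ln p_m,

where p_m is the frequency of the m-th unique class among the votes at
that voxel — zero exactly at unanimity, at most ln(n_classes).  The
literature often files this under "aleatoric" uncertainty although the
stack mixes augmentation and ensemble variability; we report it as-is and
call it vote entropy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial.transform import Rotation

from .io_prep import LabelMap, RoiConfig, Volume, extract_rois, unpad

__all__ = [
    "TtaConfig",
    "SpatialTransform",
    "EnsemblePrediction",
    "tta_augment",
    "plurality_vote",
    "uncertainty_map",
    "fuse_votes",
    "predict_crop",
    "segment",
]


@dataclass
class TtaConfig:
    n_versions: int = 21
    flip_prob: float = 0.5
    flip_axis: int = 0               # left-right axis of the crop
    affine_prob: float = 0.75
    rotation_degrees: float = 10.0
    scale_range: tuple = (0.9, 1.1)
    elastic_prob: float = 0.5
    elastic_sigma: float = 4.0       # smoothing of the displacement field (voxels)
    elastic_magnitude: float = 1.5   # peak displacement (voxels)
    include_identity: bool = False   # make version 0 the untransformed crop
    seed: int = 0

    def __post_init__(self):
        if self.n_versions < 1:
            raise ValueError("n_versions must be >= 1")
        if not (0 <= self.flip_prob <= 1):
            raise ValueError("flip_prob must be a probability")
        lo, hi = self.scale_range
        if lo <= 0 or hi <= 0 or lo > hi:
            raise ValueError("scale_range bounds must be positive and ordered "
                             "(non-invertible transform otherwise)")
        if self.elastic_sigma <= 0 or self.elastic_magnitude < 0:
            raise ValueError("invalid elastic parameters")


class SpatialTransform:
    """An invertible spatial augmentation: affine (incl. flip) + elastic field.

    Sampling convention (pull-back): the augmented image at voxel v samples
    the native image at ``A @ v + u(v)``, with A a 4x4 voxel-space matrix
    fixing the crop center and u a smooth displacement field (or None).
    """

    def __init__(self, matrix=None, displacement=None):
        self.matrix = np.eye(4) if matrix is None else np.asarray(matrix, float)
        if abs(np.linalg.det(self.matrix[:3, :3])) < 1e-9:
            raise ValueError("non-invertible augmentation matrix")
        self.displacement = displacement

    @property
    def is_identity(self):
        return self.displacement is None and np.allclose(self.matrix, np.eye(4))

    def _forward_coords(self, shape):
        grid = np.indices(shape, dtype=np.float64)
        lin = self.matrix[:3, :3]
        coords = np.einsum("ij,jdhw->idhw", lin, grid)
        coords += self.matrix[:3, 3].reshape(3, 1, 1, 1)
        if self.displacement is not None:
            coords += self.displacement
        return coords

    def _inverse_coords(self, shape):
        # exact inverse of the affine part; elastic approximated by the
        # negated displacement evaluated at the affinely-mapped position
        inv = np.linalg.inv(self.matrix)
        grid = np.indices(shape, dtype=np.float64)
        coords = np.einsum("ij,jdhw->idhw", inv[:3, :3], grid)
        coords += inv[:3, 3].reshape(3, 1, 1, 1)
        if self.displacement is not None:
            lin = inv[:3, :3]
            disp = np.stack([
                ndimage.map_coordinates(self.displacement[i], coords,
                                        order=1, mode="nearest")
                for i in range(3)])
            coords -= np.einsum("ij,jdhw->idhw", lin, disp)
        return coords

    def apply_image(self, data, order=1):
        return ndimage.map_coordinates(np.asarray(data, np.float64),
                                       self._forward_coords(data.shape),
                                       order=order, mode="nearest")

    def apply_labels(self, data):
        return ndimage.map_coordinates(data, self._forward_coords(data.shape),
                                       order=0, mode="constant", cval=0)

    def invert_labels(self, data):
        """Map a label map predicted in augmented space back to native space."""
        return ndimage.map_coordinates(data, self._inverse_coords(data.shape),
                                       order=0, mode="constant", cval=0)


@dataclass
class EnsemblePrediction:
    """Aligned per-(member x version) votes plus the fused map and entropy."""

    votes: np.ndarray          # (K, D, H, W) integer labels, native crop space
    fused: np.ndarray          # (D, H, W) plurality labels
    uncertainty: np.ndarray    # (D, H, W) vote entropy (nats)


def _random_transform(cfg: TtaConfig, shape, rng) -> SpatialTransform:
    center = (np.asarray(shape) - 1) / 2.0
    lin = np.eye(3)
    if rng.random() < cfg.flip_prob:
        flip = np.eye(3)
        flip[cfg.flip_axis, cfg.flip_axis] = -1.0
        lin = lin @ flip
    if rng.random() < cfg.affine_prob:
        angles = rng.uniform(-cfg.rotation_degrees, cfg.rotation_degrees, 3)
        scale = rng.uniform(*cfg.scale_range)
        lin = lin @ Rotation.from_euler("xyz", angles, degrees=True).as_matrix()
        lin = lin * scale
    matrix = np.eye(4)
    matrix[:3, :3] = lin
    matrix[:3, 3] = center - lin @ center
    disp = None
    if rng.random() < cfg.elastic_prob and cfg.elastic_magnitude > 0:
        raw = rng.standard_normal((3,) + tuple(shape))
        disp = np.stack([ndimage.gaussian_filter(raw[i], cfg.elastic_sigma)
                         for i in range(3)])
        peak = np.abs(disp).max()
        if peak > 0:
            disp *= cfg.elastic_magnitude / peak
    return SpatialTransform(matrix, disp)


def tta_augment(crop: np.ndarray, cfg: TtaConfig):
    """Generate exactly ``cfg.n_versions`` augmented copies of a crop.

    Returns a list of ``(augmented_data, SpatialTransform)``; the transform
    carries everything needed to map a prediction back to native space.
    Reproducible: the sequence is a pure function of ``cfg.seed``.
    """
    crop = np.asarray(crop)
    rng = np.random.default_rng(cfg.seed)
    out = []
    for i in range(cfg.n_versions):
        if i == 0 and cfg.include_identity:
            t = SpatialTransform()
        else:
            t = _random_transform(cfg, crop.shape, rng)
        out.append((t.apply_image(crop), t))
    return out


def plurality_vote(votes: np.ndarray) -> np.ndarray:
    """Voxel-wise modal class; ties broken toward the lowest class id."""
    votes = np.asarray(votes)
    if votes.ndim == 3:
        votes = votes[None]
    if votes.shape[0] == 0:
        raise ValueError("empty vote stack")
    counts = _vote_counts(votes)
    return np.argmax(counts, axis=0).astype(np.int16)   # argmax -> lowest id on ties


def _vote_counts(votes):
    n_classes = int(votes.max()) + 1
    counts = np.zeros((n_classes,) + votes.shape[1:], dtype=np.int32)
    for c in range(n_classes):
        counts[c] = (votes == c).sum(axis=0)
    return counts


def uncertainty_map(votes: np.ndarray) -> np.ndarray:
    """Vote entropy -sum_m p_m ln p_m over the unique voted classes."""
    votes = np.asarray(votes)
    if votes.ndim == 3:
        votes = votes[None]
    if votes.shape[0] == 0:
        raise ValueError("empty vote stack")
    p = _vote_counts(votes).astype(np.float64) / votes.shape[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, -p * np.log(p), 0.0)
    return terms.sum(axis=0)


def fuse_votes(votes: np.ndarray) -> EnsemblePrediction:
    votes = np.asarray(votes)
    return EnsemblePrediction(votes=votes, fused=plurality_vote(votes),
                              uncertainty=uncertainty_map(votes))


def predict_crop(crop: np.ndarray, models, tta_cfg: TtaConfig) -> EnsemblePrediction:
    """TTA + ensemble prediction of one preprocessed crop.

    Ensemble members and augmented versions are pooled into a single vote
    stack of ``len(models) * n_versions`` aligned predictions.
    """
    versions = tta_augment(crop, tta_cfg)
    votes = []
    for aug, transform in versions:
        for m in models:
            pred = m.predict(aug)
            votes.append(transform.invert_labels(pred))
    return fuse_votes(np.stack(votes))


def segment(volume: Volume, models, template: Volume, atlas: LabelMap,
            roi_labels, roi_cfg: RoiConfig, tta_cfg: TtaConfig,
            transform=None):
    """Full pipeline on a native scan: ROI extraction, TTA-ensemble
    prediction per side, and re-embedding into native volume space.

    Returns ``(LabelMap, Volume)`` — the fused segmentation and the vote
    entropy, both on the input grid (background where no ROI was predicted).
    """
    crops = extract_rois(volume, template, atlas, roi_labels, roi_cfg,
                         transform=transform)
    full_labels = np.zeros(volume.shape, dtype=np.int16)
    full_unc = np.zeros(volume.shape, dtype=np.float64)
    for i, crop in enumerate(crops):
        side_cfg = TtaConfig(**{**tta_cfg.__dict__, "seed": tta_cfg.seed + i})
        pred = predict_crop(crop.data, models, side_cfg)
        fused = unpad(pred.fused, crop.pad)
        unc = unpad(pred.uncertainty, crop.pad)
        if crop.side == "right" and roi_cfg.mirror_right:
            fused, unc = fused[::-1], unc[::-1]
        sl = crop.box.slices()
        region = full_labels[sl]
        fg = fused > 0
        region[fg] = fused[fg]
        full_labels[sl] = region
        full_unc[sl] = np.maximum(full_unc[sl], unc)
    return (LabelMap(data=full_labels, affine=volume.affine.copy()),
            Volume(data=full_unc, affine=volume.affine.copy()))
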