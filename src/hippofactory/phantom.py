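"""Synthetic hippocampus phantoms, head scenes and lifespan cohorts.

Every stage of the pipeline is exercised on data from this module, so the
generators emulate exactly the statistical structure the pipeline assumes:

* a curved tube (quadratically bent centerline, the classic "banana")
  partitioned radially into a DG core surrounded by SUB/CA1/CA2/CA3
  angular sectors, with optional undifferentiated HEAD/TAIL caps at the
  anterior/posterior ends;
* class-dependent mean intensities modulated by a smooth multiplicative
  bias field plus additive Gaussian noise;
* a larger "head" scene embedding a left phantom and its mirrored right
  twin at known affine poses, together with a template/atlas pair at the
  canonical pose (emulating an MNI-space template with a labelled atlas);
* subject cohorts whose per-region volumes follow smooth
  growth/plateau/decay trends with sex offsets and noise.

All randomness flows from a single integer seed through a named
numpy Generator; identical spec + seed gives bit-identical output.

The geometry is deliberately parametric rather than anatomically
realistic: it reproduces the head-body-tail topology and the radial
subfield arrangement needed by the anteroposterior composition profile
while remaining analytically checkable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_prep import BoundingBox, LabelMap, Volume
from .loss import CANONICAL_LABELS, CANONICAL_NAMES, SUBFIELD_NAMES, ProtocolSpec

__all__ = [
    "PhantomSpec",
    "LifespanSpec",
    "SceneBundle",
    "make_hippocampus_phantom",
    "make_head_scene",
    "make_lifespan_cohort",
    "make_protocol_variants",
    "generating_curve",
    "DEFAULT_INTENSITIES",
    "DEFAULT_REGION_PARAMS",
]

# Mean intensities (arbitrary units) per canonical class.  Values are
# spread widely enough that the classes are separable under the default
# noise, the way subfields differ in contrast on a good T2w scan.
DEFAULT_INTENSITIES = {
    "BG": 0.15,
    "DG": 1.00,
    "CA1": 0.72,
    "CA2": 0.50,
    "CA3": 0.32,
    "SUB": 0.86,
    "HEAD": 0.60,
    "TAIL": 0.42,
}


@dataclass
class PhantomSpec:
    grid_shape: tuple = (32, 32, 32)
    curvature: float = 0.35          # relative banana bend of the centerline
    class_intensities: dict = field(default_factory=lambda: dict(DEFAULT_INTENSITIES))
    noise_sd: float = 0.05           # additive Gaussian noise, intensity units
    bias_amplitude: float = 0.2      # relative amplitude of the bias field
    include_head_tail: bool = True
    head_fraction: float = 0.18      # anterior cap, fraction of tube length
    tail_fraction: float = 0.18      # posterior cap
    radius_fraction: float = 0.30    # tube radius / min transverse grid size
    seed: int = 0

    def __post_init__(self):
        self.grid_shape = tuple(int(s) for s in self.grid_shape)
        if len(self.grid_shape) != 3 or min(self.grid_shape) < 16:
            raise ValueError("grid_shape must be 3 axes of >= 16 voxels")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.bias_amplitude < 0:
            raise ValueError("bias_amplitude must be >= 0")


# ---------------------------------------------------------------------------
# single-hippocampus phantom


def carve_labels(spec: PhantomSpec, coords) -> np.ndarray:
    """Evaluate the analytic tube geometry at continuous phantom coordinates.

    `coords` has shape (3, ...) in phantom voxel units (anteroposterior
    axis = axis 1).  Because the geometry is a function of continuous
    coordinates, the same phantom can be sampled exactly on any grid —
    the native grid, or a transformed scene grid — without label
    resampling artifacts.
    """
    n0, n1, n2 = spec.grid_shape
    x0, x1, x2 = (np.asarray(c, dtype=float) for c in coords)

    j0, j1 = 0.12 * n1, 0.88 * n1                  # tube extent along axis 1
    t = (x1 - j0) / max(j1 - j0, 1e-9)
    r0 = spec.radius_fraction * min(n0, n2)
    mid0, mid2 = (n0 - 1) / 2.0, (n2 - 1) / 2.0
    bend = spec.curvature * n0 / 4.0

    c0 = mid0 + bend * ((2 * t - 1) ** 2 - 0.5)    # bent centerline
    radius = r0 * (0.72 + 1.12 * t * (1 - t))      # tapered toward both ends
    di, dk = x0 - c0, x2 - mid2
    rho = np.hypot(di, dk)
    inside = (t >= 0) & (t <= 1) & (rho <= radius)
    core = inside & (rho <= 0.45 * radius)
    theta = np.arctan2(dk, di)

    labels = np.zeros(t.shape, dtype=np.int16)
    sector = np.select(
        [theta < -np.pi / 2, theta < 0.0, theta < np.pi / 2],
        [CANONICAL_LABELS["SUB"], CANONICAL_LABELS["CA1"],
         CANONICAL_LABELS["CA2"]],
        default=CANONICAL_LABELS["CA3"])
    labels[inside] = sector[inside]
    labels[core] = CANONICAL_LABELS["DG"]
    if spec.include_head_tail:
        labels[inside & (t < spec.head_fraction)] = CANONICAL_LABELS["HEAD"]
        labels[inside & (t > 1 - spec.tail_fraction)] = CANONICAL_LABELS["TAIL"]
    return labels


def _tube_labels(spec: PhantomSpec):
    """Label map on the phantom's own grid."""
    return carve_labels(spec, np.indices(spec.grid_shape))


def _bias_field_at(spec: PhantomSpec, coords):
    """Deterministic smooth multiplicative field 1 + amplitude * P(u),
    P a fixed low-order polynomial with values in [-1, 1] over the phantom,
    evaluated at continuous phantom coordinates."""
    u0, u1, u2 = (2.0 * np.asarray(c, float) / (n - 1) - 1.0
                  for c, n in zip(coords, spec.grid_shape))
    poly = 0.5 * (u0 + u1 * u2)
    return 1.0 + spec.bias_amplitude * poly


def _bias_field(spec: PhantomSpec):
    return _bias_field_at(spec, np.indices(spec.grid_shape))


def make_hippocampus_phantom(spec: PhantomSpec):
    """Generate one hippocampus phantom: (intensity Volume, ground-truth LabelMap).

    Intensity = class mean x bias field + Gaussian noise; the label map is
    noise-free and depends only on the geometry (not the seed).
    """
    labels = _tube_labels(spec)

    requested = {k for k in spec.class_intensities if k != "BG"}
    unknown = requested - set(CANONICAL_LABELS)
    if unknown:
        raise ValueError(f"unknown classes in class_intensities: {sorted(unknown)}")
    if not spec.include_head_tail:
        requested -= {"HEAD", "TAIL"}
    present = {CANONICAL_NAMES[c] for c in np.unique(labels)}
    missing = requested - present
    if missing:
        raise ValueError(
            f"grid {spec.grid_shape} too small to carve class(es) "
            f"{sorted(missing)}; enlarge the grid or drop the class")

    intens = np.full(max(CANONICAL_LABELS.values()) + 1,
                     spec.class_intensities.get("BG", 0.0))
    for name, mean in spec.class_intensities.items():
        intens[CANONICAL_LABELS[name]] = mean

    image = intens[labels] * _bias_field(spec)
    rng = np.random.default_rng(spec.seed)
    if spec.noise_sd > 0:
        image = image + rng.normal(0.0, spec.noise_sd, size=spec.grid_shape)

    schema = {int(c): CANONICAL_NAMES[int(c)] for c in np.unique(labels)}
    return (Volume(data=image),
            LabelMap(data=labels, schema=schema))


def random_phantom_spec(seed: int, **overrides) -> PhantomSpec:
    """A PhantomSpec with randomized geometry (seeded), for building
    training/evaluation sets whose phantoms differ in shape and not just
    in noise."""
    rng = np.random.default_rng(seed)
    params = dict(
        curvature=rng.uniform(0.2, 0.5),
        radius_fraction=rng.uniform(0.26, 0.34),
        head_fraction=rng.uniform(0.14, 0.22),
        tail_fraction=rng.uniform(0.14, 0.22),
        bias_amplitude=rng.uniform(0.1, 0.3),
        seed=seed,
    )
    params.update(overrides)
    return PhantomSpec(**params)


# ---------------------------------------------------------------------------
# head scene with two phantoms at known poses


@dataclass
class SceneBundle:
    """A native-like scene plus its template/atlas pair and ground truth."""

    scene: Volume
    scene_labels: LabelMap
    template: Volume
    atlas: LabelMap
    pose_left: np.ndarray
    pose_right: np.ndarray
    box_left: BoundingBox
    box_right: BoundingBox

    def ground_truth_sidecar(self):
        return {
            "pose_left": self.pose_left.tolist(),
            "pose_right": self.pose_right.tolist(),
            "box_left": self.box_left.to_dict(),
            "box_right": self.box_right.to_dict(),
        }


def canonical_poses(spec: PhantomSpec, scene_shape):
    """Default left/right poses: phantoms side by side about the mid-sagittal
    plane (axis 0), centered in the scene."""
    ph = np.asarray(spec.grid_shape)
    sc = np.asarray(scene_shape)
    gap = ph[0] // 4
    left = np.eye(4)
    left[:3, 3] = [(sc[0] // 2) - ph[0] - gap // 2,
                   (sc[1] - ph[1]) // 2, (sc[2] - ph[2]) // 2]
    right = np.eye(4)
    right[:3, 3] = [(sc[0] // 2) + gap // 2,
                    (sc[1] - ph[1]) // 2, (sc[2] - ph[2]) // 2]
    return left, right


def _pose_box(lab, pose, scene_shape, margin=0):
    """Ground-truth bounding box of foreground voxels mapped through a pose."""
    pts = np.argwhere(lab > 0).astype(float)
    mapped = pts @ np.asarray(pose)[:3, :3].T + np.asarray(pose)[:3, 3]
    lo = np.floor(mapped.min(axis=0)).astype(int) - margin
    hi = np.floor(mapped.max(axis=0)).astype(int) + 1 + margin
    if np.any(lo < 0) or np.any(hi > scene_shape):
        raise ValueError("pose places the phantom outside the scene "
                         f"field of view (box {lo.tolist()}..{hi.tolist()}, "
                         f"scene {tuple(scene_shape)})")
    return BoundingBox(lo, hi)


def _head_ellipsoid(scene_shape, center, semiaxes, intensity=0.35):
    grids = np.meshgrid(*[np.arange(s) for s in scene_shape], indexing="ij")
    q = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semiaxes))
    return np.where(q <= 1.0, intensity, 0.05)


def make_head_scene(spec: PhantomSpec, pose_left=None, pose_right=None,
                    scene_shape=None) -> SceneBundle:
    """Embed a left phantom and its mirrored right twin into a head scene.

    Poses are 4x4 voxel-space affines (phantom -> scene).  The returned
    template/atlas pair is the same construction at the canonical poses,
    with atlas labels 1 (left hippocampus) and 2 (right); the template's
    background "head" ellipsoid is placed relative to the phantom poses so
    a global pose change moves the whole scene content coherently.
    """
    if scene_shape is None:
        scene_shape = tuple(int(3 * s) for s in spec.grid_shape)
    _, lab = make_hippocampus_phantom(spec)    # validates the spec geometry
    lab_l, lab_r = lab.data, lab.data[::-1].copy()

    canon_l, canon_r = canonical_poses(spec, scene_shape)
    if pose_left is None:
        pose_left = canon_l
    if pose_right is None:
        pose_right = canon_r
    pose_left = np.asarray(pose_left, dtype=float)
    pose_right = np.asarray(pose_right, dtype=float)
    for name, p in (("pose_left", pose_left), ("pose_right", pose_right)):
        if abs(np.linalg.det(p[:3, :3])) < 1e-12:
            raise ValueError(f"{name} is not invertible")

    mirror = np.eye(4)
    mirror[0, 0] = -1.0
    mirror[0, 3] = spec.grid_shape[0] - 1.0       # axis-0 flip in phantom frame

    intens = np.full(max(CANONICAL_LABELS.values()) + 1,
                     spec.class_intensities.get("BG", 0.0))
    for cname, mean in spec.class_intensities.items():
        intens[CANONICAL_LABELS[cname]] = mean
    grid = np.indices(scene_shape, dtype=np.float64)

    def side_labels(pose, mirrored):
        """Carve one phantom analytically on the scene grid (no label
        resampling: the geometry is evaluated at back-mapped coordinates)."""
        back = np.linalg.inv(pose)
        if mirrored:
            back = mirror @ back
        coords = np.einsum("ij,j...->i...", back[:3, :3], grid)
        coords += back[:3, 3].reshape(3, 1, 1, 1)
        return carve_labels(spec, coords), coords

    def build(pl, pr, noise_rng):
        # explicit FOV check (mapped phantom foreground must stay inside)
        box_l = _pose_box(lab_l, pl, scene_shape)
        box_r = _pose_box(lab_r, pr, scene_shape)
        lab_sl, coords_l = side_labels(pl, mirrored=False)
        lab_sr, coords_r = side_labels(pr, mirrored=True)
        labs = np.where(lab_sl > 0, lab_sl, lab_sr).astype(np.int16)

        center = (np.asarray(box_l.lo) + box_l.hi + box_r.lo + box_r.hi) / 4.0
        mean_scale = 0.5 * (np.abs(np.linalg.det(pl[:3, :3])) ** (1 / 3)
                            + np.abs(np.linalg.det(pr[:3, :3])) ** (1 / 3))
        semiaxes = mean_scale * np.asarray(spec.grid_shape) * np.array([1.4, 1.0, 1.0])
        img = _head_ellipsoid(scene_shape, center, semiaxes)
        for side_lab, coords in ((lab_sl, coords_l), (lab_sr, coords_r)):
            fg = side_lab > 0
            bias = _bias_field_at(spec, coords)
            img[fg] = (intens[side_lab] * bias)[fg]
        if spec.noise_sd > 0:
            img = img + noise_rng.normal(0.0, spec.noise_sd, size=img.shape)
        return img, labs, box_l, box_r

    rng = np.random.default_rng(spec.seed)
    scene_img, scene_lab, box_l, box_r = build(pose_left, pose_right, rng)
    tpl_img, tpl_lab, *_ = build(canon_l, canon_r,
                                 np.random.default_rng(spec.seed + 1))
    lab_tl, _ = side_labels(canon_l, mirrored=False)
    lab_tr, _ = side_labels(canon_r, mirrored=True)
    atlas = np.zeros(scene_shape, dtype=np.int16)
    atlas[lab_tl > 0] = 1
    atlas[lab_tr > 0] = 2

    return SceneBundle(
        scene=Volume(data=scene_img),
        scene_labels=LabelMap(data=scene_lab, schema=dict(CANONICAL_NAMES)),
        template=Volume(data=tpl_img),
        atlas=LabelMap(data=atlas, schema={1: "left", 2: "right"}),
        pose_left=pose_left, pose_right=pose_right,
        box_left=box_l, box_right=box_r)


# ---------------------------------------------------------------------------
# lifespan cohort generator

# Plateau volumes (mm^3) loosely on the scale of adult subfield volumetry;
# growth/decay slopes in mm^3 per year.  Males carry a +5% plateau offset
# and steeper slopes (the sex-by-age interaction the analysis stage must
# detect).  (growth_slope, plateau, decay_slope) per sex.
DEFAULT_REGION_PARAMS = {
    "whole": {"F": (45.0, 3500.0, -28.0), "M": (58.0, 3675.0, -38.0)},
    "DG":    {"F": (14.0, 900.0, -9.0),   "M": (19.0, 945.0, -13.0)},
    "CA1":   {"F": (16.0, 1300.0, -10.0), "M": (21.0, 1365.0, -14.0)},
    "CA2-3": {"F": (5.0, 500.0, -3.5),    "M": (7.0, 525.0, -5.0)},
    "SUB":   {"F": (9.0, 700.0, -6.0),    "M": (12.0, 735.0, -8.5)},
}


@dataclass
class LifespanSpec:
    n_subjects: int = 400
    age_range: tuple = (5.0, 100.0)
    knot_ages: tuple = (22.0, 70.0)      # end of growth, onset of decay
    blend_years: float = 6.0             # half-width of the smooth knee
    region_params: dict = field(default_factory=lambda: {
        r: dict(s) for r, s in DEFAULT_REGION_PARAMS.items()})
    noise_sd: float = 40.0               # mm^3
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 10:
            raise ValueError("n_subjects must be >= 10")
        lo, hi = self.age_range
        if not (0 <= lo < hi <= 120):
            raise ValueError("age_range must be within [0, 120]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _smooth_hinge(x, knot, w):
    """C1 ramp: 0 before knot-w, (x-knot) after knot+w, quadratic between."""
    x = np.asarray(x, dtype=float)
    out = np.where(x >= knot + w, x - knot, 0.0)
    blend = (x > knot - w) & (x < knot + w)
    out = np.where(blend, (x - knot + w) ** 2 / (4.0 * w), out)
    return out


def generating_curve(age, params, knot_ages, blend_years=6.0):
    """Noiseless volume trend: growth slope to a plateau, then decay.

    Piecewise polynomial (linear tails, quadratic C1 blends at the knots,
    hence everywhere a polynomial of degree <= 3), continuous by
    construction.  `params` = (growth_slope, plateau_level, decay_slope).
    """
    g, plateau, d = params
    k1, k2 = knot_ages
    w = blend_years

    def raw(x):
        x = np.asarray(x, dtype=float)
        return (g * x
                + (0.0 - g) * _smooth_hinge(x, k1, w)
                + (d - 0.0) * _smooth_hinge(x, k2, w))

    mid = 0.5 * (k1 + k2)
    return raw(age) + (plateau - raw(mid))


def make_lifespan_cohort(spec: LifespanSpec) -> pd.DataFrame:
    """Long-format subject table: subject_id, age, sex, region, volume_mm3."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    ages = rng.uniform(*spec.age_range, size=n)
    sexes = np.array(["F", "M"])[(np.arange(n) % 2)]
    rng.shuffle(sexes)

    rows = []
    for region, per_sex in spec.region_params.items():
        for sex in ("F", "M"):
            if sex not in per_sex:
                continue
            idx = np.where(sexes == sex)[0]
            curve = generating_curve(ages[idx], per_sex[sex],
                                     spec.knot_ages, spec.blend_years)
            if np.any(curve <= 0):
                raise ValueError(f"generating curve for {region}/{sex} is "
                                 "non-positive within the age range")
            vols = curve + rng.normal(0.0, spec.noise_sd, size=idx.size)
            vols = np.maximum(vols, 1.0)    # volumes are physical, keep > 0
            for i, v in zip(idx, vols):
                rows.append((f"sub-{i:04d}", ages[i], sex, region, v))
    df = pd.DataFrame(rows, columns=["subject_id", "age", "sex", "region",
                                     "volume_mm3"])
    return df.sort_values(["region", "subject_id"], ignore_index=True)


# ---------------------------------------------------------------------------
# protocol variants


def make_protocol_variants(labelmap: LabelMap, protocol: ProtocolSpec,
                           head_mask=None, tail_mask=None) -> LabelMap:
    """Relabel a canonical ground truth the way a rater following the given
    protocol would have drawn it.

    Merge groups collapse to the smallest member id (e.g. CA2+CA3 -> the
    CA2 id, read as "CA2-3").  With `protocol.head`/`tail`, subfield voxels
    inside the head/tail region (existing HEAD/TAIL labels, or the supplied
    geometric masks) become the undifferentiated cap label.  The total
    foreground voxel count is conserved.
    """
    data = labelmap.data.copy()
    n = max(CANONICAL_LABELS.values()) + 1
    if data.max() >= n or data.min() < 0:
        raise ValueError("label map contains non-canonical labels")

    table = np.arange(n)
    for g in protocol.merge_groups:
        ids = sorted(CANONICAL_LABELS[c] for c in g)
        for i in ids:
            table[i] = ids[0]
    out = table[data]

    subfield_ids = [CANONICAL_LABELS[s] for s in SUBFIELD_NAMES]
    for flag, mask, cap in ((protocol.head, head_mask, "HEAD"),
                            (protocol.tail, tail_mask, "TAIL")):
        if not flag:
            continue
        cap_id = CANONICAL_LABELS[cap]
        region = (labelmap.data == cap_id)
        if mask is not None:
            region = region | (np.asarray(mask, bool) & (labelmap.data > 0))
        out[region & np.isin(labelmap.data, subfield_ids + [cap_id])] = cap_id

    schema = {int(c): CANONICAL_NAMES[int(c)] for c in np.unique(out)}
    return LabelMap(data=out.astype(labelmap.data.dtype),
                    affine=labelmap.affine.copy(), schema=schema)
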