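"""Protocol-aware focal Tversky loss.

The base loss per class is ``L = (1 - TP / (TP + beta*FN + alpha*FP))**gamma``
with soft confusion counts (sums of per-voxel probability mass), alpha = 0.3
and beta = 0.7 weighting false positives vs. false negatives, and a focal
exponent gamma (default 3/4; the exponent is deliberately configurable —
see LossConfig).

Because manual raters follow different conventions, the loss is modulated
per observation by a :class:`ProtocolSpec`:

* classes a protocol does not distinguish (e.g. CA2 and CA3) are merged —
  their predicted probability channels are summed before scoring;
* protocols with an undifferentiated head or tail class pool *all* subfield
  probability inside head/tail target voxels into that class, so predicting
  any subfield there is rewarded as a hit, while subfield predictions
  outside head/tail are scored normally.

All operations accept either numpy arrays or autograd Tensors (channel-first
``(C, D, H, W)`` score maps), so the same code path serves training and
plain evaluation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import _autograd as ag

logger = logging.getLogger(__name__)

__all__ = [
    "CANONICAL_LABELS",
    "CANONICAL_NAMES",
    "SUBFIELD_NAMES",
    "LossConfig",
    "ProtocolSpec",
    "ConfusionCounts",
    "confusion_counts",
    "focal_tversky",
    "merge_predictions",
    "apply_head_tail_rule",
    "observation_loss",
]

# Canonical label schema shared by the phantom generator, the network and
# the loss: background plus five subfields plus optional head/tail caps.
CANONICAL_LABELS = {
    "BG": 0,
    "DG": 1,
    "CA1": 2,
    "CA2": 3,
    "CA3": 4,
    "SUB": 5,
    "HEAD": 6,
    "TAIL": 7,
}
CANONICAL_NAMES = {v: k for k, v in CANONICAL_LABELS.items()}
SUBFIELD_NAMES = ("DG", "CA1", "CA2", "CA3", "SUB")


@dataclass
class LossConfig:
    alpha: float = 0.3      # false-positive weight
    beta: float = 0.7       # false-negative weight
    gamma: float = 0.75     # focal exponent
    class_aggregation: str = "mean"   # 'mean' | 'sum'

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be >= 0")
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        if self.class_aggregation not in ("mean", "sum"):
            raise ValueError("class_aggregation must be 'mean' or 'sum'")


@dataclass
class ProtocolSpec:
    """How a particular rater protocol maps onto the canonical classes.

    merge_groups: sets of canonical subfield names scored as one class.
    head / tail: whether the protocol labels an undifferentiated head/tail
    cap (scored with subfield pooling inside those voxels).
    """

    merge_groups: tuple = ()
    head: bool = False
    tail: bool = False
    name: str = "identity"

    def __post_init__(self):
        groups = []
        seen = set()
        for g in self.merge_groups:
            g = frozenset(g)
            for cls in g:
                if cls not in CANONICAL_LABELS or cls in ("BG", "HEAD", "TAIL"):
                    raise ValueError(f"unknown canonical subfield class {cls!r} "
                                     f"in merge group")
                if cls in seen:
                    raise ValueError(f"class {cls!r} appears in two merge groups")
                seen.add(cls)
            groups.append(g)
        self.merge_groups = tuple(groups)

    @property
    def is_identity(self):
        return not self.merge_groups and not self.head and not self.tail

    def channel_groups(self, n_classes: int):
        """Partition of canonical channel ids [0, n_classes) into scored groups.

        Singleton groups for unmerged classes; merged groups keep the order
        of their smallest member id.
        """
        assigned = {}
        for g in self.merge_groups:
            ids = sorted(CANONICAL_LABELS[c] for c in g)
            if any(i >= n_classes for i in ids):
                raise ValueError(f"merge group {sorted(g)} references channels "
                                 f"outside the {n_classes}-class model")
            for i in ids:
                assigned[i] = tuple(ids)
        groups, done = [], set()
        for c in range(n_classes):
            if c in done:
                continue
            g = assigned.get(c, (c,))
            groups.append(list(g))
            done.update(g)
        return groups

    def relabel_table(self, n_classes: int):
        """Canonical label id -> merged group index."""
        groups = self.channel_groups(n_classes)
        table = np.zeros(n_classes, dtype=int)
        for gi, g in enumerate(groups):
            for c in g:
                table[c] = gi
        return table

    def group_names(self, n_classes: int):
        return ["-".join(CANONICAL_NAMES[c] for c in g)
                for g in self.channel_groups(n_classes)]


@dataclass
class ConfusionCounts:
    """Per-class soft confusion counts (probability mass sums)."""

    tp: object
    fp: object
    fn: object
    tn: object


def _data(x):
    return x.data if isinstance(x, ag.Tensor) else np.asarray(x)


def _one_hot(labels, n_classes, dtype=np.float64):
    labels = np.asarray(labels)
    out = np.zeros((n_classes,) + labels.shape, dtype=dtype)
    for c in range(n_classes):
        out[c] = labels == c
    return out


def confusion_counts(scores, onehot_target) -> ConfusionCounts:
    """Soft per-class counts from a (C, ...) score map and one-hot target."""
    y = onehot_target
    axes = tuple(range(1, _data(scores).ndim))
    tp = (scores * y).sum(axis=axes)
    fp = (scores * (1.0 - y)).sum(axis=axes)
    fn = ((1.0 - scores) * y).sum(axis=axes)
    tn = ((1.0 - scores) * (1.0 - y)).sum(axis=axes)
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def focal_tversky(counts: ConfusionCounts, cfg: LossConfig):
    """Per-class focal Tversky loss ``(1 - TI)**gamma``, TI the Tversky index.

    Classes with all-zero counts are left as NaN-safe placeholders (their
    denominator is stabilised) — callers mask them out of the aggregation.
    """
    tp, fp, fn = counts.tp, counts.fp, counts.fn
    raw = _data(tp) + cfg.beta * _data(fn) + cfg.alpha * _data(fp)
    stabil = np.where(raw <= 0, 1e-12, 0.0)   # 0/0 guard (absent classes
    # or zero-weighted errors); such classes score (1-0)^gamma and are
    # masked out by callers when absent from the ground truth
    denom = tp + cfg.beta * fn + cfg.alpha * fp + stabil
    ti = tp / denom
    return (1.0 - ti) ** cfg.gamma


def _group_matrix(groups, n_classes):
    m = np.zeros((len(groups), n_classes))
    for gi, g in enumerate(groups):
        for c in g:
            m[gi, c] = 1.0
    return m


def _matmul_channels(scores, m):
    """Apply a (G, C) channel-mixing matrix to a (C, ...) score map."""
    m = m.astype(_data(scores).dtype)
    if isinstance(scores, ag.Tensor):
        return ag.conv1x1(scores, ag.constant(m))
    flat = np.asarray(scores).reshape(scores.shape[0], -1)
    return (m @ flat).reshape((m.shape[0],) + scores.shape[1:])


def merge_predictions(scores, protocol: ProtocolSpec):
    """Sum probability channels of classes a protocol does not distinguish."""
    n_classes = _data(scores).shape[0]
    groups = protocol.channel_groups(n_classes)
    if len(groups) == n_classes:
        return scores
    return _matmul_channels(scores, _group_matrix(groups, n_classes))


def apply_head_tail_rule(scores, target, protocol: ProtocolSpec,
                         group_names=None):
    """Pool subfield probability into the head/tail channel inside head/tail
    target voxels.

    `scores` and `target` live in the protocol's merged group space
    (`target` as integer group indices).  Outside head/tail voxels nothing
    changes, so stray head/tail (or subfield) predictions there remain
    penalized.
    """
    if not (protocol.head or protocol.tail):
        return scores, target
    n_groups = _data(scores).shape[0]
    if group_names is None:
        group_names = protocol.group_names(n_groups)
    name_to_idx = {n: i for i, n in enumerate(group_names)}
    subfield_idx = [i for i, n in enumerate(group_names)
                    if set(n.split("-")) <= set(SUBFIELD_NAMES)]
    target_arr = np.asarray(_data(target))

    out = scores
    for flag, cap in ((protocol.head, "HEAD"), (protocol.tail, "TAIL")):
        if not flag or cap not in name_to_idx:
            continue
        cap_idx = name_to_idx[cap]
        mask = (target_arr == cap_idx).astype(_data(scores).dtype)[None]
        pool = np.eye(n_groups)
        for s in subfield_idx:
            pool[s, s] = 0.0
            pool[cap_idx, s] = 1.0
        pooled = _matmul_channels(out, pool)
        out = out * (1.0 - mask) + pooled * mask
    return out, target


def observation_loss(scores, target, protocol: ProtocolSpec, cfg: LossConfig):
    """Protocol-modulated focal Tversky loss for one observation.

    `scores`: (C, D, H, W) class probabilities (numpy or Tensor).
    `target`: integer canonical label map (D, H, W).
    Returns a scalar (Tensor if `scores` is a Tensor).
    """
    n_classes = _data(scores).shape[0]
    table = protocol.relabel_table(n_classes)
    target = np.asarray(_data(target)).astype(int)
    if target.max() >= n_classes:
        raise ValueError(f"target contains label {target.max()} outside the "
                         f"{n_classes}-class model")
    merged_target = table[target]
    merged_scores = merge_predictions(scores, protocol)
    group_names = protocol.group_names(n_classes)

    merged_scores, merged_target = apply_head_tail_rule(
        merged_scores, merged_target, protocol, group_names)

    n_groups = len(group_names)
    onehot = _one_hot(merged_target, n_groups, dtype=_data(merged_scores).dtype)
    counts = confusion_counts(merged_scores, onehot)
    losses = focal_tversky(counts, cfg)

    # classes absent from this observation's ground truth are skipped, not
    # scored as (vacuously perfect) zeros
    present = (_data(counts.tp) + _data(counts.fn)) > 0
    if not present.any():
        raise ValueError("no scoreable class in observation")
    if not present.all():
        logger.debug("skipping absent classes: %s",
                     [group_names[i] for i in np.where(~present)[0]])
    weights = present.astype(np.float64)
    total = (losses * weights).sum()
    if cfg.class_aggregation == "mean":
        total = total * (1.0 / float(weights.sum()))
    return total
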