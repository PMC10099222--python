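"""Segmentation metrics (Dice, 95th-percentile Hausdorff) and the training
loss (soft Dice + cross-entropy).

Conventions fixed for reproducibility:

* boundaries use 6-connectivity; the volume border counts as background;
* distances are Euclidean in millimetres (anisotropic ``spacing`` scales
  each axis);
* the 95th percentile is taken over each directed boundary-distance set
  separately (linear interpolation between order statistics) and the two
  directed values are combined with ``max``; percentile 100 recovers the
  classic Hausdorff distance;
* if exactly one mask is empty the distance is undefined and returned as
  NaN (callers decide the aggregation policy); two empty masks give 0.
"""
from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from ._tensor import Tensor, log_softmax, softmax

__all__ = [
    "dice_score", "extract_boundary", "hausdorff_distance", "hausdorff95",
    "region_masks", "dice_ce_loss", "BRATS_LABELS",
]

# label encoding of the nested brain-tumour scheme
BRATS_LABELS = {"background": 0, "necrotic": 1, "edema": 2, "enhancing": 3}

_STRUCT6 = ndimage.generate_binary_structure(3, 1)


def _as_bool(m) -> np.ndarray:
    return np.asarray(m).astype(bool)


def dice_score(pred, ref) -> float:
    """Overlap 2|P n G| / (|P| + |G|); 1.0 when both masks are empty."""
    P, G = _as_bool(pred), _as_bool(ref)
    if P.shape != G.shape:
        raise ValueError(f"mask shapes differ: {P.shape} vs {G.shape}")
    denom = int(P.sum()) + int(G.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int(np.logical_and(P, G).sum()) / denom


def extract_boundary(mask) -> np.ndarray:
    """Voxel coordinates (N, 3) of mask voxels with a face-adjacent
    background or out-of-volume neighbour."""
    M = _as_bool(mask)
    if not M.any():
        return np.empty((0, M.ndim), dtype=np.int64)
    inner = ndimage.binary_erosion(M, structure=_STRUCT6, border_value=0)
    return np.argwhere(M & ~inner)


def _directed_percentile(src: np.ndarray, dst_tree: cKDTree, q: float) -> float:
    d, _ = dst_tree.query(src, k=1, workers=-1)
    return float(np.percentile(d, q))


def hausdorff_distance(pred, ref, spacing=(1.0, 1.0, 1.0),
                       percentile: float = 100.0) -> float:
    """Percentile Hausdorff distance between mask boundaries, in mm.

    ``percentile=100`` is the classic max-min Hausdorff distance; 95 the
    robust HD95.  NaN when exactly one mask is empty; 0 when both are.
    """
    P, G = _as_bool(pred), _as_bool(ref)
    if P.shape != G.shape:
        raise ValueError(f"mask shapes differ: {P.shape} vs {G.shape}")
    if not P.any() and not G.any():
        return 0.0
    if not P.any() or not G.any():
        return float("nan")
    sp = np.asarray(spacing, dtype=np.float64)
    pb = extract_boundary(P) * sp
    gb = extract_boundary(G) * sp
    d_pg = _directed_percentile(pb, cKDTree(gb), percentile)
    d_gp = _directed_percentile(gb, cKDTree(pb), percentile)
    return max(d_pg, d_gp)


def hausdorff95(pred, ref, spacing=(1.0, 1.0, 1.0)) -> float:
    return hausdorff_distance(pred, ref, spacing, percentile=95.0)


def region_masks(labels, scheme: str = "brats") -> dict:
    """Composite evaluation regions from a label volume.

    ``brats``: ET = enhancing; TC = enhancing u necrotic; WT = TC u edema
    (nested ET c TC c WT).  ``organs``: one mask per positive label.
    """
    lab = np.asarray(labels)
    if scheme == "brats":
        et = lab == BRATS_LABELS["enhancing"]
        tc = et | (lab == BRATS_LABELS["necrotic"])
        wt = tc | (lab == BRATS_LABELS["edema"])
        return {"WT": wt, "TC": tc, "ET": et}
    if scheme == "organs":
        return {f"organ{v}": lab == v for v in np.unique(lab) if v > 0}
    raise ValueError(f"unknown region scheme {scheme!r}")


def dice_ce_loss(scores: Tensor, target, eps: float = 1e-5) -> Tensor:
    """Sum of soft multiclass Dice loss and voxel-mean cross-entropy.

    ``scores``: (B, C, D, H, W) class logits (a leading batch axis is added
    if missing); ``target``: integer labels (B, D, H, W).  The Dice term
    averages the per-class soft Dice over the foreground classes; both terms
    are differentiable and the sum is non-negative.
    """
    if not isinstance(scores, Tensor):
        scores = Tensor(scores)
    target = np.asarray(target)
    if scores.ndim == 4:
        scores = scores.reshape(1, *scores.shape)
    if target.ndim == 3:
        target = target[None]
    ncls = scores.shape[1]
    if scores.shape[0] != target.shape[0] or scores.shape[2:] != target.shape[1:]:
        raise ValueError(f"scores {scores.shape} incompatible with target "
                         f"{target.shape}")
    onehot = np.moveaxis(np.eye(ncls, dtype=np.float32)[target], -1, 1)
    ls = log_softmax(scores, axis=1)
    ce = -(ls * Tensor(onehot)).sum(axis=1).mean()
    probs = softmax(scores, axis=1)
    ax = (0, 2, 3, 4)
    inter = (probs * Tensor(onehot)).sum(axis=ax)
    sums = probs.sum(axis=ax) + Tensor(onehot.sum(axis=ax))
    dsc = (inter * 2.0 + eps) / (sums + eps)      # per-class soft Dice
    fg = dsc[1:]                                   # drop background
    dice_loss = 1.0 - fg.mean()
    return dice_loss + ce
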