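"""Synthetic phantoms, NIfTI I/O, preprocessing and dataset splits.

The phantom generator makes the whole pipeline testable without downloading
scanner data.  The ``brats`` scheme draws a background head ellipsoid with a
nested tumour inside it - edema shell (whole tumour) containing a core
containing an enhancing centre, mirroring the nested WT/TC/ET evaluation
regions of multi-modal brain MRI - and gives each of the K channels its own
region contrast pattern plus Gaussian noise.  The ``organs`` scheme places
disjoint ellipsoid "organs" on a single-channel volume, loosely emulating
abdominal CT label maps.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "Phantom", "generate_phantom", "generate_dataset", "save_case",
    "load_case", "preprocess", "split_dataset", "SPLIT_SCHEMES",
]

# per-channel intensity offsets added on top of the background tissue level
# (channels cycle through the rows); contrasts are O(1) so signal-to-noise is
# set directly by ``noise_sd``
_BRATS_CONTRAST = np.array([
    # edema  core  enhancing
    [0.6, -0.5, 0.9],
    [-0.7, 0.8, 1.4],
    [1.0, 0.5, -0.6],
    [1.2, 0.7, 0.6],
], dtype=np.float32)
_ORGAN_CONTRAST = np.array([0.8, -0.6, 1.2, 0.5, -1.0, 1.5], dtype=np.float32)
_BACKGROUND_LEVEL = 1.0


@dataclass
class Phantom:
    """A synthetic case: ``image`` (K, D, H, W), ``labels`` (D, H, W)."""

    image: np.ndarray
    labels: np.ndarray
    meta: dict = field(default_factory=dict)


def _ellipsoid(shape, center, radii) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    return acc <= 1.0


def generate_phantom(seed: int, size: int = 32, scheme: str = "brats",
                     K: int = 4, noise_sd: float = 0.2,
                     n_organs: int = 3) -> Phantom:
    """Deterministic phantom for the given seed.

    ``brats``: labels 1 = necrotic core, 2 = edema, 3 = enhancing, nested so
    that ET c TC c WT always holds.  ``organs``: labels 1..n_organs on
    disjoint ellipsoids.
    """
    if scheme not in ("brats", "organs"):
        raise ValueError(f"unknown phantom scheme {scheme!r}")
    rng = np.random.default_rng(seed)
    shape = (size, size, size)
    labels = np.zeros(shape, dtype=np.uint8)
    image = np.zeros((K,) + shape, dtype=np.float32)
    head_r = np.full(3, 0.42 * size)
    center = np.array(shape) / 2.0
    head = _ellipsoid(shape, center, head_r)

    if scheme == "brats":
        c = center + rng.uniform(-0.08, 0.08, 3) * size
        r_wt = rng.uniform(0.18, 0.26, 3) * size
        r_tc = r_wt * rng.uniform(0.55, 0.7, 3)
        r_et = r_tc * rng.uniform(0.5, 0.65, 3)
        wt = _ellipsoid(shape, c, r_wt) & head
        tc = _ellipsoid(shape, c, r_tc) & wt
        et = _ellipsoid(shape, c, r_et) & tc
        labels[wt] = 2            # edema
        labels[tc] = 1            # necrotic core
        labels[et] = 3            # enhancing
        regions = [wt & ~tc, tc & ~et, et]
        for ch in range(K):
            base = np.where(head, _BACKGROUND_LEVEL, 0.0).astype(np.float32)
            offs = _BRATS_CONTRAST[ch % len(_BRATS_CONTRAST)]
            for reg, off in zip(regions, offs):
                base[reg] += off
            if noise_sd > 0:
                base[head] += rng.normal(0.0, noise_sd,
                                         int(head.sum())).astype(np.float32)
            image[ch] = base
        meta_r = {"wt": r_wt.tolist(), "tc": r_tc.tolist(), "et": r_et.tolist()}
    else:
        anchors = np.linspace(0.25, 0.75, n_organs)
        meta_r = {}
        for k in range(n_organs):
            c = np.array([anchors[k] * size,
                          center[1] + rng.uniform(-0.08, 0.08) * size,
                          center[2] + rng.uniform(-0.08, 0.08) * size])
            r = rng.uniform(0.06, 0.10, 3) * size
            organ = _ellipsoid(shape, c, r) & head & (labels == 0)
            labels[organ] = k + 1
            meta_r[f"organ{k + 1}"] = r.tolist()
        for ch in range(K):
            base = np.where(head, _BACKGROUND_LEVEL, 0.0).astype(np.float32)
            for k in range(n_organs):
                base[labels == k + 1] += _ORGAN_CONTRAST[(ch + k) % len(_ORGAN_CONTRAST)]
            if noise_sd > 0:
                base[head] += rng.normal(0.0, noise_sd,
                                         int(head.sum())).astype(np.float32)
            image[ch] = base
    meta = {"seed": int(seed), "size": int(size), "scheme": scheme, "K": int(K),
            "noise_sd": float(noise_sd), "radii": meta_r}
    return Phantom(image=image, labels=labels, meta=meta)


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------
def save_case(case_dir, image: np.ndarray, labels: np.ndarray,
              affine: np.ndarray | None = None, meta: dict | None = None) -> dict:
    """Write one case as image.nii.gz (D, H, W, K) + labels.nii.gz."""
    case_dir = Path(case_dir)
    case_dir.mkdir(parents=True, exist_ok=True)
    affine = np.eye(4) if affine is None else np.asarray(affine, dtype=float)
    img4d = np.moveaxis(np.asarray(image, dtype=np.float32), 0, -1)
    paths = {"image": str(case_dir / "image.nii.gz"),
             "labels": str(case_dir / "labels.nii.gz")}
    nib.save(nib.Nifti1Image(img4d, affine), paths["image"])
    nib.save(nib.Nifti1Image(np.asarray(labels, dtype=np.uint8), affine),
             paths["labels"])
    if meta is not None:
        (case_dir / "meta.json").write_text(json.dumps(meta, indent=1))
    return paths


def load_case(case_dir) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Load a saved case; returns (image (K, D, H, W), labels, affine)."""
    case_dir = Path(case_dir)
    img = nib.load(case_dir / "image.nii.gz")
    lab = nib.load(case_dir / "labels.nii.gz")
    image = np.moveaxis(np.asarray(img.dataobj, dtype=np.float32), -1, 0)
    labels = np.asarray(lab.dataobj).astype(np.uint8)
    if image.shape[1:] != labels.shape:
        raise ValueError(f"image grid {image.shape[1:]} does not match label "
                         f"grid {labels.shape}")
    if not np.allclose(img.affine, lab.affine):
        raise ValueError("image and label affines differ")
    return image, labels, img.affine


def generate_dataset(root, n: int, size: int = 32, scheme: str = "brats",
                     seed: int = 0, K: int = 4, noise_sd: float = 0.2) -> dict:
    """Write ``n`` phantoms under ``root`` plus a manifest.json."""
    root = Path(root)
    manifest = {"scheme": scheme, "size": size, "K": K, "noise_sd": noise_sd,
                "seed": seed, "cases": {}}
    for i in range(n):
        cid = f"case_{i:04d}"
        ph = generate_phantom(seed * 100003 + i, size, scheme, K, noise_sd)
        paths = save_case(root / cid, ph.image, ph.labels, meta=ph.meta)
        manifest["cases"][cid] = paths
    (root / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------
def _zscore_nonzero(image: np.ndarray) -> np.ndarray:
    out = image.astype(np.float32).copy()
    for ch in range(out.shape[0]):
        nz = out[ch] != 0
        if nz.any():
            mu = out[ch][nz].mean()
            sd = out[ch][nz].std()
            out[ch][nz] = (out[ch][nz] - mu) / (sd if sd > 1e-8 else 1.0)
    return out


def preprocess(image: np.ndarray, labels: np.ndarray | None, crop: int,
               mode: str = "eval", rng: np.random.Generator | None = None,
               flip: bool = True) -> tuple[np.ndarray, np.ndarray | None]:
    """Crop to ``crop``^3 (random in train mode, centred otherwise), z-score
    each channel over its nonzero voxels, and optionally flip (train only).

    Volumes smaller than the crop are zero-padded symmetrically first.
    """
    if mode not in ("train", "eval"):
        raise ValueError(f"mode must be 'train' or 'eval', got {mode!r}")
    if mode == "train" and rng is None:
        rng = np.random.default_rng()
    image = np.asarray(image, dtype=np.float32)
    if labels is not None:
        labels = np.asarray(labels)
    pads = [(0, 0)]
    for ax in range(3):
        short = max(0, crop - image.shape[1 + ax])
        pads.append((short // 2, short - short // 2))
    if any(p != (0, 0) for p in pads[1:]):
        image = np.pad(image, pads)
        if labels is not None:
            labels = np.pad(labels, pads[1:])
    starts = []
    for ax in range(3):
        room = image.shape[1 + ax] - crop
        starts.append(int(rng.integers(0, room + 1)) if mode == "train" else room // 2)
    sl = tuple(slice(s, s + crop) for s in starts)
    image = image[(slice(None),) + sl]
    if labels is not None:
        labels = labels[sl]
    image = _zscore_nonzero(image)
    if mode == "train" and flip:
        for ax in range(3):
            if rng.random() < 0.5:
                image = np.flip(image, 1 + ax)
                if labels is not None:
                    labels = np.flip(labels, ax)
        image = np.ascontiguousarray(image)
        if labels is not None:
            labels = np.ascontiguousarray(labels)
    return image, labels


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------
SPLIT_SCHEMES = {
    "brats": (834, 208, 209),   # of 1251 scans
    "liver": (87, 22, 22),      # of 131 volumes
    "btcv": (24, 6, 20),        # of 50 volumes
}


def split_dataset(case_ids, scheme="brats", seed: int = 0) -> dict:
    """Deterministic shuffled train/val/test split.

    ``scheme`` is a named convention from :data:`SPLIT_SCHEMES` or an
    explicit (train, val, test) count/proportion triple.  For datasets whose
    size differs from the convention's, the proportions are applied with the
    largest-remainder method (which reproduces the canonical sizes exactly
    at the canonical dataset size).
    """
    ids = list(case_ids)
    counts = SPLIT_SCHEMES[scheme] if isinstance(scheme, str) else tuple(scheme)
    total = sum(counts)
    n = len(ids)
    quota = [c * n / total for c in counts]
    sizes = [int(q) for q in quota]
    rema = sorted(range(3), key=lambda i: quota[i] - sizes[i], reverse=True)
    for i in rema[:n - sum(sizes)]:
        sizes[i] += 1
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(n))
    out, start = {}, 0
    for name, s in zip(("train", "val", "test"), sizes):
        out[name] = [ids[i] for i in order[start:start + s]]
        start += s
    assert sum(len(v) for v in out.values()) == n
    assert len(set().union(*map(set, out.values()))) == n, "overlapping splits"
    return out
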