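"""Leaf/background segmentation, mean-spectrum extraction, sub-block
splitting, centered padding, dataset partitioning, and augmentation.

Segmentation exploits the leaf/background contrast at 800 nm (leaves are
bright on the NIR plateau, the dark background is not): Otsu's threshold on
the 800 nm grayscale, then largest-component + hole-fill cleanup.

Dataset handling enforces the leakage rule: leaves are partitioned into
train/validation/test folds *before* sub-blocking, so every sub-block (and
every augmented copy) inherits its parent leaf's fold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from skimage import measure

from .cube_io import HyperspectralCube, band_index

__all__ = [
    "LeafSample",
    "DatasetPartition",
    "otsu_threshold",
    "segment_leaf",
    "extract_mean_spectrum",
    "split_subblocks",
    "pad_center",
    "partition_dataset",
    "augment_set",
    "AUGMENTATION_OPS",
]


@dataclass
class LeafSample:
    """A cube + binary mask + class label with provenance.

    ``block_index`` 0 means the whole leaf; sub-blocks carry 1..k and share
    their parent's ``leaf_id``.
    """

    cube: HyperspectralCube
    mask: np.ndarray
    label: int
    leaf_id: int
    block_index: int = 0

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=np.uint8)
        if self.mask.shape != self.cube.shape[:2]:
            raise ValueError(
                f"mask shape {self.mask.shape} != cube spatial shape {self.cube.shape[:2]}"
            )
        if not 1 <= self.label <= 6:
            raise ValueError("label must be in 1..6")
        if self.block_index < 0:
            raise ValueError("block_index must be >= 0")


@dataclass(frozen=True)
class DatasetPartition:
    """Leaf-level train/validation/test split (disjoint leaf_ids)."""

    train: tuple
    validation: tuple
    test: tuple
    seed: int

    def __post_init__(self):
        folds = [set(self.train), set(self.validation), set(self.test)]
        total = sum(len(f) for f in folds)
        if len(folds[0] | folds[1] | folds[2]) != total:
            raise ValueError("folds must be disjoint at the leaf level")

    def fold_of(self, leaf_id) -> str:
        if leaf_id in set(self.train):
            return "train"
        if leaf_id in set(self.validation):
            return "validation"
        if leaf_id in set(self.test):
            return "test"
        raise KeyError(leaf_id)


# ---------------------------------------------------------------------------
# Otsu threshold and segmentation
# ---------------------------------------------------------------------------

def otsu_threshold(image: np.ndarray, nbins: int = 256) -> float:
    """Threshold maximizing between-class variance on an ``nbins`` histogram.

    The histogram spans [min, max] of the image; the returned threshold is
    the bin edge of the maximizing cut, ties resolved to the lowest edge.
    """
    image = np.asarray(image, dtype=np.float64)
    if not np.all(np.isfinite(image)):
        raise ValueError("image must be finite")
    if nbins < 2:
        raise ValueError("nbins must be >= 2")
    lo, hi = float(image.min()), float(image.max())
    if lo == hi:
        raise ValueError("degenerate histogram: constant image")
    counts, edges = np.histogram(image.ravel(), bins=nbins, range=(lo, hi))
    counts = counts.astype(np.float64)
    total = counts.sum()
    centers = 0.5 * (edges[:-1] + edges[1:])
    w0 = np.cumsum(counts)[:-1]                      # class 0 = bins 0..k
    w1 = total - w0
    csum = np.cumsum(counts * centers)[:-1]
    mu0 = np.where(w0 > 0, csum / np.maximum(w0, 1), 0.0)
    mu1 = np.where(w1 > 0, (csum[-1] + counts[-1] * centers[-1] - csum) / np.maximum(w1, 1), 0.0)
    valid = (w0 > 0) & (w1 > 0)
    sigma_b = np.where(valid, w0 * w1 * (mu0 - mu1) ** 2, -np.inf)
    k = int(np.argmax(sigma_b))                      # argmax takes the first tie
    return float(edges[k + 1])


def segment_leaf(cube: HyperspectralCube, ref_nm: float = 800.0) -> np.ndarray:
    """Binary leaf mask from the Otsu-thresholded band nearest ``ref_nm``.

    The foreground is the class with the higher mean reflectance at the
    reference band (leaves are bright in the NIR); cleanup keeps the largest
    8-connected component and fills holes.
    """
    band = cube.data[:, :, band_index(cube.axis, ref_nm)].astype(np.float64)
    t = otsu_threshold(band)
    fg = band > t
    if fg.any() and (~fg).any():
        if band[fg].mean() < band[~fg].mean():
            fg = ~fg
    labels = measure.label(fg, connectivity=2)
    if labels.max() == 0:
        raise ValueError("no leaf found: empty foreground")
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    fg = labels == int(np.argmax(sizes))
    fg = ndimage.binary_fill_holes(fg)
    if fg.mean() < 0.005:
        raise ValueError(
            f"no leaf found: foreground covers {fg.mean():.2%} of pixels (< 0.5%)"
        )
    return fg.astype(np.uint8)


def extract_mean_spectrum(cube: HyperspectralCube, mask: np.ndarray) -> np.ndarray:
    """Per-band arithmetic mean of the foreground pixels."""
    mask = np.asarray(mask).astype(bool)
    if mask.shape != cube.shape[:2]:
        raise ValueError("mask shape does not match cube")
    if not mask.any():
        raise ValueError("empty mask")
    return cube.data[mask].mean(axis=0, dtype=np.float64)


# ---------------------------------------------------------------------------
# Sub-blocks, padding
# ---------------------------------------------------------------------------

def _bbox(mask: np.ndarray):
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    if rows.size == 0:
        raise ValueError("empty mask")
    return rows[0], rows[-1] + 1, cols[0], cols[-1] + 1  # half-open


def subblock_windows(L: int, k: int, overlap: float = 0.25):
    """k half-open windows along an axis of length L.

    Window length starts from ``L_w = ceil(L / (k - (k-1)*overlap))`` with
    uniformly spaced starts; because integer rounding can push a short
    window's shared fraction to the 30% cap, L_w is reduced (down to the
    gap-free minimum ``ceil(L/k)``) until every pairwise shared-length/L_w
    is strictly below 0.30 and the windows still cover [0, L).
    """
    if not 2 <= k <= 4:
        raise ValueError("k must be in 2..4")
    if L < k:
        raise ValueError(f"axis length {L} too short for {k} sub-blocks")
    Lw0 = min(math.ceil(L / (k - (k - 1) * overlap)), L)
    for Lw in range(Lw0, max(math.ceil(L / k), 1) - 1, -1):
        starts = [int(round(i * (L - Lw) / (k - 1))) for i in range(k)]
        windows = [(s, s + Lw) for s in starts]
        shared = [max(0, e1 - s2) for (_, e1), (s2, _) in zip(windows, windows[1:])]
        covered = all(s2 <= e1 for (_, e1), (s2, _) in zip(windows, windows[1:]))
        if covered and all(sh / Lw < 0.30 for sh in shared):
            return windows
    raise ValueError(f"no admissible window layout for L={L}, k={k}")


def choose_k(long_axis_length: int) -> int:
    """2-4 sub-blocks by leaf long-axis length (< 150 px -> 2, < 250 -> 3, else 4)."""
    if long_axis_length < 150:
        return 2
    if long_axis_length < 250:
        return 3
    return 4


def split_subblocks(sample: LeafSample, k: int, overlap: float = 0.25):
    """Split a whole-leaf sample into k overlapping sub-blocks along the
    longer bounding-box axis; each carries the cropped cube + mask, the
    parent ``leaf_id`` and ``block_index`` 1..k."""
    r0, r1, c0, c1 = _bbox(sample.mask)
    h, w = r1 - r0, c1 - c0
    along_rows = h >= w
    L = h if along_rows else w
    windows = subblock_windows(L, k, overlap)
    out = []
    for i, (s, e) in enumerate(windows, start=1):
        if along_rows:
            rows = slice(r0 + s, r0 + e)
            cols = slice(c0, c1)
        else:
            rows = slice(r0, r1)
            cols = slice(c0 + s, c0 + e)
        sub_cube = HyperspectralCube(
            sample.cube.data[rows, cols, :].copy(), sample.cube.axis,
            sample.cube.interleave_hint,
        )
        out.append(
            LeafSample(sub_cube, sample.mask[rows, cols].copy(), sample.label,
                       sample.leaf_id, block_index=i)
        )
    return out


def _nn_resize(arr: np.ndarray, new_h: int, new_w: int) -> np.ndarray:
    h, w = arr.shape[:2]
    ri = np.clip((np.arange(new_h) + 0.5) * h / new_h, 0, h - 1).astype(int)
    ci = np.clip((np.arange(new_w) + 0.5) * w / new_w, 0, w - 1).astype(int)
    return arr[np.ix_(ri, ci)]


def pad_center(sample: LeafSample, size: int = 112) -> LeafSample:
    """Zero-value centered padding to ``size`` x ``size``.

    Background pixels are zeroed, the mask bounding box is centered in a zero
    frame; an ROI larger than ``size`` is nearest-neighbor downscaled
    (aspect preserved, longer side = ``size``) first.
    """
    r0, r1, c0, c1 = _bbox(sample.mask)
    cube = sample.cube.data * sample.mask[:, :, None]
    roi = cube[r0:r1, c0:c1, :]
    m = sample.mask[r0:r1, c0:c1]
    h, w = roi.shape[:2]
    if max(h, w) > size:
        scale = size / max(h, w)
        nh, nw = max(1, round(h * scale)), max(1, round(w * scale))
        roi = _nn_resize(roi, nh, nw)
        m = _nn_resize(m, nh, nw)
        h, w = nh, nw
    frame = np.zeros((size, size, sample.cube.n_bands), dtype=np.float32)
    mask_frame = np.zeros((size, size), dtype=np.uint8)
    top = (size - h) // 2
    left = (size - w) // 2
    frame[top:top + h, left:left + w, :] = roi
    mask_frame[top:top + h, left:left + w] = m
    padded = HyperspectralCube(frame, sample.cube.axis, sample.cube.interleave_hint)
    return replace(sample, cube=padded, mask=mask_frame)


# ---------------------------------------------------------------------------
# Partitioning and augmentation
# ---------------------------------------------------------------------------

def partition_dataset(samples, ratios=(0.6, 0.2, 0.2), seed: int = 0) -> DatasetPartition:
    """Stratified-by-class random split at the leaf level.

    Per-class fold sizes follow the largest-remainder rule, so they stay
    within one leaf of the exact 60:20:20 proportions.  Only whole-leaf
    samples (block_index 0) are accepted; sub-blocks inherit their parent's
    fold afterwards.
    """
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("ratios must sum to 1")
    if any(s.block_index != 0 for s in samples):
        raise ValueError("partition operates on whole-leaf samples only")
    by_class: dict[int, list] = {}
    for s in samples:
        by_class.setdefault(s.label, []).append(s.leaf_id)
    rng = np.random.default_rng(seed)
    folds = ([], [], [])
    for label in sorted(by_class):
        ids = sorted(by_class[label])
        if len(ids) < 5:
            raise ValueError(f"class {label} has {len(ids)} leaves (< 5)")
        ids = [ids[i] for i in rng.permutation(len(ids))]
        n = len(ids)
        raw = [n * r for r in ratios]
        base = [math.floor(x) for x in raw]
        rem = n - sum(base)
        order = np.argsort([b - x for b, x in zip(base, raw)])  # largest remainder
        for j in range(rem):
            base[order[j]] += 1
        cut1, cut2 = base[0], base[0] + base[1]
        folds[0].extend(ids[:cut1])
        folds[1].extend(ids[cut1:cut2])
        folds[2].extend(ids[cut2:])
    return DatasetPartition(tuple(folds[0]), tuple(folds[1]), tuple(folds[2]), seed)


def _op_hflip(a):
    return a[:, ::-1]


def _op_vflip(a):
    return a[::-1, :]


def _op_rot90(a):
    return np.rot90(a, 1, axes=(0, 1))


def _op_rot180(a):
    return np.rot90(a, 2, axes=(0, 1))


def _op_rot270(a):
    return np.rot90(a, 3, axes=(0, 1))


def _op_transpose(a):
    return np.swapaxes(a, 0, 1)


#: Spatial augmentation group: flips, rotations, transpose-mirror.
AUGMENTATION_OPS = (
    _op_hflip, _op_vflip, _op_rot90, _op_rot180, _op_rot270, _op_transpose,
)


def augment_set(samples, per_class_target: int = 2000, seed: int = 0):
    """Offline augmentation to ~``per_class_target`` samples per class.

    Ops are drawn uniformly from flips/rotations/transpose, applied to the
    spatial dims only (the spectral axis is untouched); originals are always
    retained; sampling is with replacement and seeded.  Requires square
    (padded) samples so every op preserves shape.
    """
    rng = np.random.default_rng(seed)
    by_class: dict[int, list] = {}
    for s in samples:
        if s.cube.shape[0] != s.cube.shape[1]:
            raise ValueError("augment_set expects square (padded) samples")
        by_class.setdefault(s.label, []).append(s)
    out = []
    for label in sorted(by_class):
        pool = by_class[label]
        out.extend(pool)
        need = per_class_target - len(pool)
        for _ in range(max(0, need)):
            src = pool[int(rng.integers(len(pool)))]
            op = AUGMENTATION_OPS[int(rng.integers(len(AUGMENTATION_OPS)))]
            aug_cube = HyperspectralCube(
                np.ascontiguousarray(op(src.cube.data)), src.cube.axis,
                src.cube.interleave_hint,
            )
            out.append(
                LeafSample(aug_cube, np.ascontiguousarray(op(src.mask)),
                           src.label, src.leaf_id, src.block_index)
            )
    return out
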