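"""Seeded synthetic hyperspectral leaf generator with ground truth.

Emulates the reflectance structure of green lemon leaves across six condition
classes (healthy; CYVCV-infected only; nitrogen-deficient; N-deficient +
CYVCV; pesticide-damaged; pesticide + CYVCV): a low blue shoulder, the green
peak near 550 nm, the chlorophyll absorption trough near 680 nm, a logistic
red edge over 680-750 nm, and the NIR high-reflection plateau above 750 nm.

Class contrasts follow the field phenomenology: the two classes with intact
chlorophyll (healthy, CYVCV-only) sit lowest in the 500-680 nm window, while
CYVCV-bearing classes lose reflectance on the NIR plateau (cell-structure and
water changes).  Within those constraints each class receives a distinct
visible offset so that all six classes are mutually separable; the template
amplitudes are stand-ins, not measurements.

Everything is seeded; every generated object comes with its ground truth
(true mask, class template, discriminative wavelength windows).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator

from .cube_io import HyperspectralCube, WavelengthAxis, working_axis

__all__ = [
    "ClassProfile",
    "SimConfig",
    "default_profiles",
    "class_reflectance",
    "simulate_leaf",
    "simulate_dataset",
    "simulate_spectra",
    "discriminative_bands",
]

#: Per-class leaf counts of the six-condition design (healthy, CYVCV-only,
#: N-deficient, N-deficient+CYVCV, pesticide, pesticide+CYVCV).
DEFAULT_CLASS_COUNTS = (90, 90, 79, 81, 90, 92)

VISIBLE_WINDOW = (500.0, 680.0)
NIR_WINDOW = (750.0, 1000.0)


@dataclass(frozen=True)
class ClassProfile:
    """Spectral offsets of one leaf condition class.

    ``visible_offset`` is added over 500-680 nm (chlorophyll window),
    ``nir_offset`` over 750-1000 nm (structure/water window); both smoothly
    windowed.  When ``vis_center`` is set, the visible offset is additionally
    shaped by a Gaussian bump of width ``vis_width`` centered there, so
    different stress types brighten different parts of the chlorophyll
    window (yellowing vs browning) rather than the window uniformly.
    """

    class_id: int
    visible_offset: float
    nir_offset: float
    jitter_sd: float = 0.02
    vis_center: float | None = None
    vis_width: float = 45.0

    def __post_init__(self):
        if not 1 <= self.class_id <= 6:
            raise ValueError("class_id must be in 1..6")


def default_profiles() -> dict[int, ClassProfile]:
    """Well-separated default class design.

    Healthy (1) and CYVCV-only (2) have no visible offset; nitrogen
    deficiency (3, 4) brightens the yellow-green region (bump at 555 nm,
    chlorosis), pesticide damage (5, 6) the orange-red region (bump at
    645 nm, browning), with a slightly larger magnitude when combined with
    infection.  CYVCV-bearing classes (2, 4, 6) lose 0.06 reflectance on the
    NIR plateau.  All six templates are mutually distinct and the class
    means are far from collinear, so both linear and kernel classifiers can
    separate them.
    """
    vis = {1: 0.0, 2: 0.0, 3: 0.05, 4: 0.065, 5: 0.05, 6: 0.065}
    center = {1: None, 2: None, 3: 555.0, 4: 555.0, 5: 645.0, 6: 645.0}
    nir = {c: (-0.06 if c in (2, 4, 6) else 0.0) for c in range(1, 7)}
    return {
        c: ClassProfile(c, vis[c], nir[c], vis_center=center[c])
        for c in range(1, 7)
    }


def hard_profiles() -> dict[int, ClassProfile]:
    """Offsets halved, jitter doubled: exercises the confusion structure."""
    import dataclasses

    return {
        c: dataclasses.replace(
            p, visible_offset=p.visible_offset / 2,
            nir_offset=p.nir_offset / 2, jitter_sd=p.jitter_sd * 2,
        )
        for c, p in default_profiles().items()
    }


@dataclass
class SimConfig:
    axis: WavelengthAxis = field(default_factory=working_axis)
    image_size: int = 96
    class_counts: tuple = DEFAULT_CLASS_COUNTS
    profiles: dict = field(default_factory=default_profiles)
    seed: int = 0

    def __post_init__(self):
        if any(c < 1 for c in self.class_counts):
            raise ValueError("class counts must be >= 1")


# ---------------------------------------------------------------------------
# Spectral templates
# ---------------------------------------------------------------------------

# Control points of the baseline green-leaf visible curve (nm, reflectance).
_VIS_POINTS = np.array([
    (300.0, 0.045),
    (400.0, 0.050),
    (450.0, 0.060),
    (500.0, 0.080),
    (550.0, 0.150),
    (600.0, 0.110),
    (650.0, 0.070),
    (680.0, 0.050),
    (720.0, 0.050),
    (1100.0, 0.050),
])

_NIR_PLATEAU = 0.48
_RED_EDGE_CENTER = 715.0
_RED_EDGE_WIDTH = 11.0


def _smooth_window(lam: np.ndarray, lo: float, hi: float, taper: float = 12.0):
    """1 inside [lo, hi], cosine-tapered to 0 over `taper` nm outside."""
    up = np.clip((lam - (lo - taper)) / taper, 0.0, 1.0)
    down = np.clip(((hi + taper) - lam) / taper, 0.0, 1.0)
    return 0.5 * (1 - np.cos(np.pi * up)) * 0.5 * (1 - np.cos(np.pi * down))


def baseline_reflectance(axis: WavelengthAxis) -> np.ndarray:
    """Healthy green-leaf baseline: visible curve blended into the NIR plateau
    through a logistic red edge, with a gentle decline past 1000 nm."""
    lam = axis.values
    vis = PchipInterpolator(_VIS_POINTS[:, 0], _VIS_POINTS[:, 1])(lam)
    edge = 1.0 / (1.0 + np.exp(-(lam - _RED_EDGE_CENTER) / _RED_EDGE_WIDTH))
    plateau = _NIR_PLATEAU - 0.04 * np.clip((lam - 1000.0) / 90.0, 0.0, 1.0)
    return vis * (1 - edge) + plateau * edge


def class_reflectance(
    class_id: int, axis: WavelengthAxis, profiles: dict | None = None
) -> np.ndarray:
    """Template spectrum of one class: baseline plus smoothly-windowed
    visible and NIR offsets.  Raises if the result leaves [0, 1]."""
    profiles = profiles or default_profiles()
    prof = profiles[class_id]
    lam = axis.values
    t = baseline_reflectance(axis)
    vis_shape = _smooth_window(lam, *VISIBLE_WINDOW)
    if prof.vis_center is not None:
        vis_shape = vis_shape * np.exp(
            -0.5 * ((lam - prof.vis_center) / prof.vis_width) ** 2
        )
    t = t + prof.visible_offset * vis_shape
    t = t + prof.nir_offset * _smooth_window(lam, *NIR_WINDOW)
    if t.min() < 0.0 or t.max() > 1.0:
        raise ValueError(
            f"class {class_id} template leaves [0, 1]: "
            f"range [{t.min():.3f}, {t.max():.3f}]"
        )
    return t


def discriminative_bands(config: SimConfig | None = None) -> list[tuple[float, float]]:
    """Wavelength intervals where at least two class templates differ by more
    than 0.01 reflectance — the ground truth for selection-recovery tests."""
    config = config or SimConfig()
    axis = config.axis
    templates = np.stack(
        [class_reflectance(c, axis, config.profiles) for c in range(1, 7)]
    )
    diff = np.zeros(len(axis), dtype=bool)
    for i in range(6):
        for j in range(i + 1, 6):
            diff |= np.abs(templates[i] - templates[j]) > 0.01
    return _bool_to_intervals(diff, axis.values)


def _bool_to_intervals(mask: np.ndarray, lam: np.ndarray) -> list[tuple[float, float]]:
    intervals = []
    in_run = False
    for i, m in enumerate(mask):
        if m and not in_run:
            start = lam[i]
            in_run = True
        elif not m and in_run:
            intervals.append((float(start), float(lam[i - 1])))
            in_run = False
    if in_run:
        intervals.append((float(start), float(lam[-1])))
    return intervals


def in_discriminative_window(
    wavelengths: np.ndarray, intervals: list[tuple[float, float]], slack_nm: float = 0.0
) -> np.ndarray:
    """Boolean per wavelength: inside any ground-truth interval (+/- slack)."""
    wavelengths = np.atleast_1d(wavelengths)
    hit = np.zeros(wavelengths.shape, dtype=bool)
    for lo, hi in intervals:
        hit |= (wavelengths >= lo - slack_nm) & (wavelengths <= hi + slack_nm)
    return hit


# ---------------------------------------------------------------------------
# Leaf images
# ---------------------------------------------------------------------------

BACKGROUND_LEVEL = 0.02


def _elliptical_mask(size: int, rng: np.random.Generator) -> np.ndarray:
    """Leaf-shaped mask: rotated ellipse with sinusoidal boundary perturbation."""
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    cy = size / 2 + rng.uniform(-size * 0.03, size * 0.03)
    cx = size / 2 + rng.uniform(-size * 0.03, size * 0.03)
    a = size * rng.uniform(0.30, 0.42)          # semi-major
    ratio = rng.uniform(1.4, 2.6)
    b = a / ratio                               # semi-minor
    theta = rng.uniform(0, np.pi)
    ct, st = np.cos(theta), np.sin(theta)
    u = (xx - cx) * ct + (yy - cy) * st
    v = -(xx - cx) * st + (yy - cy) * ct
    r = np.sqrt((u / a) ** 2 + (v / b) ** 2)
    ang = np.arctan2(v / b, u / a)
    n_lobes = rng.integers(3, 7)
    phase = rng.uniform(0, 2 * np.pi)
    wobble = 1.0 + 0.06 * np.sin(n_lobes * ang + phase)
    return (r <= wobble).astype(np.uint8)


def _brightness_field(size: int, rng: np.random.Generator) -> np.ndarray:
    """Smooth multiplicative field, mean ~1, +/- 10%."""
    yy, xx = np.mgrid[0:size, 0:size] / size
    fy, fx = rng.uniform(0.5, 1.5, size=2)
    py, px = rng.uniform(0, 2 * np.pi, size=2)
    f = np.sin(2 * np.pi * fy * yy + py) * np.sin(2 * np.pi * fx * xx + px)
    return 1.0 + 0.10 * f


def simulate_leaf(
    class_id: int,
    axis: WavelengthAxis | None = None,
    size: int = 96,
    seed: int = 0,
    profiles: dict | None = None,
):
    """Simulate one leaf cube plus its ground-truth mask.

    Returns ``(cube, true_mask)``.  Foreground = class template x smooth
    brightness field (+/- 10%) + per-pixel Gaussian jitter; background is
    near-zero reflectance (~0.02) so the NIR band is Otsu-separable.
    """
    if size < 64:
        raise ValueError("size must be >= 64")
    axis = axis or working_axis()
    profiles = profiles or default_profiles()
    rng = np.random.default_rng(seed)
    template = class_reflectance(class_id, axis, profiles).astype(np.float32)
    B = len(axis)
    mask = _elliptical_mask(size, rng)
    bright = _brightness_field(size, rng).astype(np.float32)
    jitter_sd = profiles[class_id].jitter_sd

    data = rng.normal(BACKGROUND_LEVEL, 0.005, size=(size, size, B)).astype(np.float32)
    fg = mask.astype(bool)
    n_fg = int(fg.sum())
    leaf = (
        bright[fg][:, None] * template[None, :]
        + rng.normal(0.0, jitter_sd, size=(n_fg, B)).astype(np.float32)
    )
    data[fg] = leaf
    np.clip(data, 0.0, 1.2, out=data)
    cube = HyperspectralCube(data, axis)
    return cube, mask


def simulate_dataset(config: SimConfig | None = None):
    """Simulate the full leaf set (default 522 leaves, counts 90/90/79/81/90/92).

    Returns a list of ``(cube, true_mask, label, leaf_id)`` tuples plus the
    discriminative-band ground truth.
    """
    config = config or SimConfig()
    ss = np.random.SeedSequence(config.seed)
    samples = []
    leaf_id = 0
    for class_id, count in zip(range(1, 7), config.class_counts):
        child_seeds = ss.spawn(count)
        for cs in child_seeds:
            seed = int(cs.generate_state(1)[0] % (2**31))
            cube, mask = simulate_leaf(
                class_id, config.axis, config.image_size, seed, config.profiles
            )
            samples.append((cube, mask, class_id, leaf_id))
            leaf_id += 1
    return samples, discriminative_bands(config)


def simulate_image_dataset(
    n_per_class: int,
    n_bands: int = 15,
    size: int = 112,
    seed: int = 0,
    profiles: dict | None = None,
    masked: bool = True,
    out: np.ndarray | None = None,
):
    """Simulate a CNN-ready image set: ``(images, labels, leaf_ids)``.

    ``images`` is (n, size, size, n_bands) float32 with the background zeroed
    (the zero-padded ROI convention) when ``masked``; the wavelength axis is
    ``n_bands`` uniform points on 400-1000 nm, as if the cube had been
    reduced to selected bands.  ``out`` may supply a preallocated image
    buffer of the right shape (reused across repeated simulations).
    """
    axis = WavelengthAxis.uniform(400.0, 1000.0, n_bands)
    profiles = profiles or default_profiles()
    ss = np.random.SeedSequence(seed)
    n_total = 6 * n_per_class
    shape = (n_total, size, size, n_bands)
    if out is not None:
        if out.shape != shape or out.dtype != np.float32:
            raise ValueError(f"out must be float32 with shape {shape}")
        images = out
    else:
        images = np.empty(shape, dtype=np.float32)
    labels = np.empty(n_total, dtype=int)
    i = 0
    for class_id in range(1, 7):
        for cs in ss.spawn(n_per_class):
            leaf_seed = int(cs.generate_state(1)[0] % (2**31))
            cube, mask = simulate_leaf(class_id, axis, size, leaf_seed, profiles)
            img = cube.data
            if masked:
                img = img * mask[:, :, None]
            images[i] = img
            labels[i] = class_id
            i += 1
    return images, labels, np.arange(n_total)


# ---------------------------------------------------------------------------
# Mean spectra (no imaging) — fast fixture for chemometrics
# ---------------------------------------------------------------------------

def simulate_spectra(
    n_per_class: int | tuple,
    axis: WavelengthAxis | None = None,
    profiles: dict | None = None,
    seed: int = 0,
    scatter: bool = True,
    band_noise_sd: float = 0.006,
    leaf_sd: float = 0.005,
):
    """Simulate per-leaf mean spectra directly (no spatial rendering).

    Each row = a x (template + leaf-level window offset + band noise) + b,
    where a ~ N(1, 0.05) and b ~ N(0, 0.01) model multiplicative/additive
    scatter (what SNV removes) and the leaf-level offset (sd ``leaf_sd``)
    perturbs the class's own contrast windows.

    Returns ``(X, y, axis)`` with labels in 1..6.
    """
    axis = axis or working_axis()
    profiles = profiles or default_profiles()
    if isinstance(n_per_class, int):
        counts = (n_per_class,) * 6
    else:
        counts = tuple(n_per_class)
    rng = np.random.default_rng(seed)
    lam = axis.values
    vis_w = _smooth_window(lam, *VISIBLE_WINDOW)
    nir_w = _smooth_window(lam, *NIR_WINDOW)
    rows, labels = [], []
    for class_id, count in zip(range(1, 7), counts):
        template = class_reflectance(class_id, axis, profiles)
        for _ in range(count):
            x = template + rng.normal(0, leaf_sd) * vis_w + rng.normal(0, leaf_sd) * nir_w
            x = x + rng.normal(0, band_noise_sd, size=lam.size)
            if scatter:
                a = 1.0 + rng.normal(0, 0.05)
                b = rng.normal(0, 0.01)
                x = a * x + b
            rows.append(x)
            labels.append(class_id)
    X = np.asarray(rows)
    y = np.asarray(labels)
    perm = rng.permutation(len(y))
    return X[perm], y[perm], axis
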