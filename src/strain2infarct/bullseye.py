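"""AHA bullseye rendering and image preprocessing.

Each strain component of an example is painted onto a polar bullseye disc:
four concentric rings carry the four short-axis levels, the apex as the
innermost disc and the base as the outer ring, with ring boundaries at
0.25/0.50/0.75/1.00 of the disc radius.  Angle zero lies along the image +x
axis and increases counterclockwise; the continuous angular profile of each
level is rendered directly (nearest angular bin).  Strain values are mapped
to [0, 1] intensities by a fixed affine map per component, and the three
greyscale maps are stacked into an RGB image with R = circumferential,
G = radial, B = longitudinal.  Pixels outside the disc are exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
from skimage.transform import resize as _sk_resize

from .library import COMPONENTS, LEVELS, GeneratorConfig, StrainExample

#: ring boundaries as fractions of the disc radius, innermost (apex) first
RING_RADII = (0.25, 0.50, 0.75, 1.00)


@dataclass
class BullseyeImage:
    """Normalized 3-channel bullseye image with its paired binary mask."""

    pixels: np.ndarray              # (H, W, 3) float32 in [0, 1]
    mask: np.ndarray                # (H, W) uint8
    meta: dict = field(default_factory=dict)

    @property
    def size(self) -> int:
        return self.pixels.shape[0]


def default_strain_ranges(config: GeneratorConfig) -> dict:
    """Fixed per-component strain->intensity ranges derived from the
    generator's healthy baselines, padded so noisy and attenuated values
    stay inside the mapped interval.  Dataset-independent by construction,
    so low- and high-fidelity domains share one mapping."""
    ranges = {}
    for k, name in enumerate(COMPONENTS):
        table = np.array([config.healthy_baseline(b + 1)[:, k]
                          for b in range(config.n_base_models)])
        pad = 6.0 * max(config.noise_amplitude, config.hf_noise_amplitude)
        amp = 1.0 + config.angular_variation
        lo = min(table.min() * amp, 0.0) - pad - abs(config.cc_bulge)
        hi = max(table.max() * amp, 0.0) + pad + abs(config.cc_bulge)
        ranges[name] = (float(lo), float(hi))
    return ranges


def strain_to_intensity(value, component: str, ranges: dict):
    """Affine map of the fixed per-component strain range to [0, 1], clipped."""
    lo, hi = ranges[component]
    return np.clip((np.asarray(value, dtype=float) - lo) / (hi - lo), 0.0, 1.0)


def _polar_lookup(size: int):
    """Per-pixel (inside-disc, level index, angular bin fraction)."""
    c = (size - 1) / 2.0
    radius = size / 2.0
    y, x = np.mgrid[0:size, 0:size]
    # image +x axis to the right, +y up (row index downward), angle CCW
    dx = (x - c) / radius
    dy = (c - y) / radius
    r = np.sqrt(dx ** 2 + dy ** 2)
    theta = np.mod(np.arctan2(dy, dx), 2.0 * np.pi)
    inside = r <= 1.0
    # innermost disc is the apex; LEVELS orders base first
    level = np.digitize(r, RING_RADII, right=True)
    level = np.clip(level, 0, 3)
    level = 3 - level  # ring index -> LEVELS index (base=0 outermost)
    return inside, level, theta


def render_bullseye(example: StrainExample, component: str,
                    size: int = 128) -> np.ndarray:
    """Paint one component's per-level angular profiles onto the disc.

    Returns an (size, size) array of raw strain values, zero outside the
    disc.
    """
    if size < 32:
        raise ValueError("size must be >= 32")
    if component not in COMPONENTS:
        raise ValueError(f"unknown component {component!r}")
    k = COMPONENTS.index(component)
    inside, level, theta = _polar_lookup(size)
    n_theta = example.strains.shape[-1]
    tbin = np.minimum((theta / (2.0 * np.pi) * n_theta).astype(int), n_theta - 1)
    out = np.where(inside, example.strains[level, k, tbin], 0.0)
    return out


def render_mask(example: StrainExample, size: int = 128) -> np.ndarray:
    """Binary infarct mask on the same bullseye geometry."""
    inside, level, theta = _polar_lookup(size)
    n_theta = example.mask.shape[-1]
    tbin = np.minimum((theta / (2.0 * np.pi) * n_theta).astype(int), n_theta - 1)
    return np.where(inside, example.mask[level, tbin], 0).astype(np.uint8)


def compose_channels(circ, rad, lng, mask=None, meta=None) -> BullseyeImage:
    """Stack intensity grids into an RGB image (R=circ, G=rad, B=long)."""
    grids = [np.asarray(g, dtype=np.float32) for g in (circ, rad, lng)]
    if len({g.shape for g in grids}) != 1:
        raise ValueError("channel grids must share one shape")
    pixels = np.stack(grids, axis=-1)
    if mask is None:
        mask = np.zeros(grids[0].shape, dtype=np.uint8)
    return BullseyeImage(pixels=pixels, mask=np.asarray(mask, dtype=np.uint8),
                         meta=dict(meta or {}))


def decompose_channels(image: BullseyeImage):
    return image.pixels[..., 0], image.pixels[..., 1], image.pixels[..., 2]


def example_to_image(example: StrainExample, size: int = 128,
                     ranges: dict | None = None,
                     config: GeneratorConfig | None = None,
                     source_id=None) -> BullseyeImage:
    """Full preprocessing of one example: render, normalize, compose."""
    if ranges is None:
        ranges = default_strain_ranges(config or GeneratorConfig())
    inside, _, _ = _polar_lookup(size)
    channels = []
    for comp in COMPONENTS:
        grid = render_bullseye(example, comp, size)
        channels.append(np.where(inside, strain_to_intensity(grid, comp, ranges), 0.0))
    meta = {"source_id": source_id, "rotation": 0, "domain": example.domain}
    return compose_channels(*channels, mask=render_mask(example, size), meta=meta)


def augment_rotations(images) -> list:
    """Original plus 90/180/270-degree rotations: a fourfold increase."""
    out = []
    for img in images:
        if img.pixels.shape[0] != img.pixels.shape[1]:
            raise ValueError("rotation augmentation requires square images")
        out.append(img)
        for k in (1, 2, 3):
            out.append(BullseyeImage(
                pixels=np.ascontiguousarray(np.rot90(img.pixels, k, axes=(0, 1))),
                mask=np.ascontiguousarray(np.rot90(img.mask, k, axes=(0, 1))),
                meta={**img.meta, "rotation": 90 * k},
            ))
    return out


def resize(image: BullseyeImage, size: int) -> BullseyeImage:
    """Resize to a square target; masks use nearest-neighbour and stay binary."""
    if size < 16 or size % 2:
        raise ValueError("target size must be an even integer >= 16")
    if size == image.size:
        return image
    pixels = _sk_resize(image.pixels, (size, size), order=1,
                        preserve_range=True, anti_aliasing=image.size > size)
    mask = _sk_resize(image.mask.astype(float), (size, size), order=0,
                      preserve_range=True, anti_aliasing=False)
    return BullseyeImage(pixels=np.clip(pixels, 0.0, 1.0).astype(np.float32),
                         mask=(mask > 0.5).astype(np.uint8),
                         meta=dict(image.meta))


@dataclass
class DatasetSplit:
    train: list
    val: list
    test: list
    fractions: tuple
    seed: int


def split_dataset(images, fractions=(0.7, 0.15, 0.15), seed=0) -> DatasetSplit:
    """Split grouped by source example so augmented copies never straddle
    splits; deterministic under the seed."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    groups = {}
    for img in images:
        groups.setdefault(img.meta.get("source_id"), []).append(img)
    ids = sorted(groups, key=lambda v: (str(type(v)), str(v)))
    rng = np.random.default_rng(seed)
    rng.shuffle(ids)
    n = len(ids)
    n_train = int(round(fractions[0] * n))
    n_val = int(round(fractions[1] * n))
    if fractions[1] > 0 and n_val == 0 and n > n_train:
        n_val = 1
    n_train = min(n_train, n)
    parts = (ids[:n_train], ids[n_train:n_train + n_val], ids[n_train + n_val:])
    buckets = []
    for part in parts:
        bucket = []
        for i in part:
            bucket.extend(groups[i])
        buckets.append(bucket)
    return DatasetSplit(train=buckets[0], val=buckets[1], test=buckets[2],
                        fractions=tuple(fractions), seed=seed)


def stack_images(images):
    """(n, H, W, 3) float32 pixel array and (n, H, W) uint8 mask array."""
    X = np.stack([img.pixels for img in images]).astype(np.float32)
    y = np.stack([img.mask for img in images]).astype(np.uint8)
    return X, y


# -- persistence ---------------------------------------------------------------

def save_dataset(path, images) -> None:
    X, y = stack_images(images)
    with h5py.File(path, "w") as f:
        f.create_dataset("pixels", data=X)
        f.create_dataset("masks", data=y)
        f.create_dataset("source_id",
                         data=np.array([str(i.meta.get("source_id"))
                                        for i in images], dtype="S"))
        f.create_dataset("rotation",
                         data=np.array([i.meta.get("rotation", 0)
                                        for i in images]))


def load_dataset(path) -> list:
    with h5py.File(path, "r") as f:
        X = f["pixels"][()]
        y = f["masks"][()]
        sid = [s.decode() for s in f["source_id"][()]]
        rot = f["rotation"][()]
    return [BullseyeImage(pixels=X[i], mask=y[i],
                          meta={"source_id": sid[i], "rotation": int(rot[i])})
            for i in range(X.shape[0])]


def save_pngs(directory, images) -> None:
    """8-bit PNG export of images and masks (one pair per example)."""
    from pathlib import Path

    from PIL import Image

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, img in enumerate(images):
        Image.fromarray((img.pixels * 255).astype(np.uint8)).save(
            directory / f"image_{i:05d}.png")
        Image.fromarray((img.mask * 255).astype(np.uint8)).save(
            directory / f"mask_{i:05d}.png")
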