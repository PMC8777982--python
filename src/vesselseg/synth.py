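"""Synthetic fundus image / vessel-mask generator.

Emulates the statistical structure the segmenter assumes — a bright
roughly circular field of view (FOV) on a dark border, non-uniform
illumination, a branching dark-on-light vessel tree occupying a target
fraction of the FOV (~9%, the scale of real retinal images), optional
bright centerline reflex, blur and additive Gaussian noise — so the whole
pipeline trains and evaluates with no external data.

The vessel tree is a recursive branching random walk (not a physiological
haemodynamic model): each branch jitters its heading by a tortuosity
parameter per unit step, paints a disc of its current width, and spawns
narrower children at random bifurcation events. Trees are added until the
rendered vessel fraction inside the FOV reaches the target, so the
fraction is tightly controlled across seeds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage

from .data import SamplePair, write_manifest
from .exceptions import GenerationError, InputError

__all__ = ["VesselTreeParams", "generate_vessel_tree", "render_fundus",
           "generate_pair", "generate_dataset", "write_catalog"]


@dataclass(frozen=True)
class VesselTreeParams:
    """Generator configuration. Lengths are pixels; the default 128 px
    preset is sized for CPU experiments, ``preset_512`` for inspection."""

    size: int = 128
    n_roots: int = 4
    max_depth: int = 4
    branch_prob: float = 0.06       # per-step bifurcation probability
    initial_width: float | None = None  # px; default scales as size/85
    width_decay: float = 0.72
    tortuosity: float = 0.18        # heading jitter std, radians per step
    vessel_contrast: float = 0.45
    illumination_gradient: float = 0.25
    noise_sigma: float = 6.0        # 8-bit intensity units
    fov_radius_frac: float = 0.95
    target_vessel_fraction: float = 0.10  # of FOV pixels, +/- 3 pp tolerated
    central_reflex: float = 0.0     # brightening factor for 1-px centerline
    seed: int = 0

    def widths(self) -> float:
        return self.initial_width if self.initial_width is not None else max(1.5, self.size / 85)

    def validate(self):
        if self.size < 16:
            raise InputError("size must be >= 16")
        if not 0 < self.width_decay < 1:
            raise InputError("width_decay must lie in (0, 1)")
        if self.widths() < 1:
            raise InputError("initial_width must be >= 1")
        if not 0 < self.fov_radius_frac <= 1:
            raise InputError("fov_radius_frac must lie in (0, 1]")
        if not 0 < self.target_vessel_fraction < 0.5:
            raise InputError("target_vessel_fraction must lie in (0, 0.5)")


def preset_512(seed: int = 0) -> VesselTreeParams:
    return VesselTreeParams(size=512, noise_sigma=5.0, central_reflex=0.25, seed=seed)


def fov_mask(size: int, radius_frac: float) -> np.ndarray:
    c = (size - 1) / 2
    yy, xx = np.mgrid[:size, :size]
    return (yy - c) ** 2 + (xx - c) ** 2 <= (radius_frac * size / 2) ** 2


_DISC_OFFSETS: dict[float, tuple[np.ndarray, np.ndarray]] = {}


def _disc_offsets(radius: float):
    """Integer (dy, dx) offsets inside a disc, cached per rounded radius."""
    key = round(radius, 1)
    if key not in _DISC_OFFSETS:
        r = max(int(math.ceil(key)), 1)
        yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
        inside = yy ** 2 + xx ** 2 <= key ** 2
        _DISC_OFFSETS[key] = (yy[inside].copy(), xx[inside].copy())
    return _DISC_OFFSETS[key]


def _paint_disc(mask, fov, x, y, radius):
    """Paint a disc clipped to the FOV; returns number of new pixels."""
    size = mask.shape[0]
    dy, dx = _disc_offsets(radius)
    ys = dy + int(round(y))
    xs = dx + int(round(x))
    ok = (ys >= 0) & (ys < size) & (xs >= 0) & (xs < size)
    if not ok.all():
        ys, xs = ys[ok], xs[ok]
    sel = fov[ys, xs] & ~mask[ys, xs]
    if not sel.any():
        return 0
    mask[ys[sel], xs[sel]] = True
    return int(sel.sum())


def generate_vessel_tree(params: VesselTreeParams) -> np.ndarray:
    """Rasterize a branching vessel tree as a (size, size) uint8 mask.

    Deterministic per seed. Trees rooted on the FOV rim grow inward until
    the vessel fraction inside the FOV reaches the target (overshoot is at
    most one painted step, well inside the +/-3 pp band).
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    size = params.size
    fov = fov_mask(size, params.fov_radius_frac)
    fov_count = int(fov.sum())
    target_px = params.target_vessel_fraction * fov_count
    mask = np.zeros((size, size), dtype=bool)
    c = (size - 1) / 2
    rim = params.fov_radius_frac * size / 2 * 0.96

    painted = 0
    trees = 0
    max_trees = max(64, 4 * params.n_roots)
    while painted < target_px and trees < max_trees:
        painted = _grow_tree(mask, fov, rng, params, c, rim, painted, target_px)
        trees += 1
        if trees >= params.n_roots and painted >= target_px:
            break
    if painted < target_px * 0.7:
        raise GenerationError(
            f"vessel fraction stalled at {painted / fov_count:.3f} after {trees} trees "
            f"(target {params.target_vessel_fraction}); widen parameters")
    return mask.astype(np.uint8)


def _grow_tree(mask, fov, rng, params, c, rim, painted, target_px):
    theta = rng.uniform(0, 2 * np.pi)
    pos = np.array([c + rim * math.cos(theta), c + rim * math.sin(theta)])
    heading = theta + np.pi + rng.normal(0, 0.35)
    stack = [(pos, heading, params.widths(), 0)]
    size = params.size
    while stack:
        pos, heading, width, depth = stack.pop()
        n_steps = int(size * 0.55 * (0.82 ** depth))
        for _ in range(n_steps):
            heading += rng.normal(0, params.tortuosity)
            pos = pos + np.array([math.cos(heading), math.sin(heading)])
            if not (-2 <= pos[0] < size + 2 and -2 <= pos[1] < size + 2):
                break
            painted += _paint_disc(mask, fov, pos[0], pos[1], width / 2)
            if painted >= target_px:
                return painted
            if depth < params.max_depth and rng.random() < params.branch_prob:
                split = rng.uniform(0.35, 0.8)
                side = 1 if rng.random() < 0.5 else -1
                stack.append((pos.copy(), heading + side * split,
                              width * params.width_decay, depth + 1))
                heading -= side * split * 0.5
                width *= max(params.width_decay, 0.85)
    return painted


def render_fundus(mask: np.ndarray, params: VesselTreeParams) -> np.ndarray:
    """Render an RGB fundus-like image from a vessel mask.

    Reddish-orange FOV disc on a near-black background, radial + linear
    illumination gradient, vessels darkened by ``vessel_contrast``,
    optional bright centerline (central vessel reflex), Gaussian blur and
    additive Gaussian noise. Deterministic per seed.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.ndim != 2 or mask.shape[0] != mask.shape[1]:
        raise InputError(f"mask must be square 2-D, got shape {mask.shape}")
    size = mask.shape[0]
    rng = np.random.default_rng((params.seed, 7919))
    fov = fov_mask(size, params.fov_radius_frac)

    c = (size - 1) / 2
    yy, xx = np.mgrid[:size, :size]
    r2 = ((yy - c) ** 2 + (xx - c) ** 2) / (size / 2) ** 2
    g = params.illumination_gradient
    tilt_dir = rng.uniform(0, 2 * np.pi)
    illum = (1.0 - g * 0.6 * r2
             + g * 0.25 * (((xx - c) * math.cos(tilt_dir)
                            + (yy - c) * math.sin(tilt_dir)) / (size / 2)))

    base = np.array([205.0, 110.0, 55.0])
    img = np.full((size, size, 3), 4.0)
    img[fov] = base * np.clip(illum, 0.2, 1.2)[fov, None]

    img[mask & fov] *= (1.0 - params.vessel_contrast)
    if params.central_reflex > 0:
        from skimage.morphology import skeletonize
        reflex = skeletonize(mask) & fov
        img[reflex] *= (1.0 + params.central_reflex)

    img = ndimage.gaussian_filter(img, sigma=(0.8, 0.8, 0))
    if params.noise_sigma > 0:
        img = img + rng.normal(0, params.noise_sigma, img.shape)
    return np.clip(img, 0, 255).astype(np.uint8)


def generate_pair(params: VesselTreeParams, sample_id: str = "synth") -> SamplePair:
    mask = generate_vessel_tree(params)
    image = render_fundus(mask, params)
    return SamplePair(id=sample_id, image=image, mask=mask)


def generate_dataset(n: int, params: VesselTreeParams | None = None,
                     seed: int = 0, out_dir=None) -> list[SamplePair]:
    """Generate ``n`` pairs with per-sample seeds ``seed + index``.

    With ``out_dir``, writes PNG images/masks and a manifest compatible
    with :mod:`vesselseg.data` (all rows tagged ``train``; re-tag or split
    with :func:`vesselseg.data.make_splits`).
    """
    if n < 1:
        raise InputError("n must be >= 1")
    base = params or VesselTreeParams()
    pairs = [generate_pair(replace(base, seed=seed + i), sample_id=f"synth_{seed + i:05d}")
             for i in range(n)]
    if out_dir is not None:
        write_catalog(pairs, out_dir)
    return pairs


def write_catalog(pairs, out_dir, splits: dict | None = None) -> Path:
    """Write PNG images + masks (vessel=255) and a manifest; returns the
    manifest path."""
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    rows = []
    for pair in pairs:
        img_rel = f"images/{pair.id}.png"
        msk_rel = f"masks/{pair.id}.png"
        iio.imwrite(out / img_rel, pair.image)
        iio.imwrite(out / msk_rel, pair.mask * 255)
        rows.append({"id": pair.id, "image": img_rel, "mask": msk_rel,
                     "split": (splits or {}).get(pair.id, "train")})
    manifest = out / "manifest.tsv"
    write_manifest(rows, manifest)
    return manifest
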