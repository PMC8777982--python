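"""Fundus image/mask catalogs: loading, manifests, splits, augmentation.

A catalog is a list of :class:`SamplePair`; on disk it is described by a
plain-text tab-separated manifest with header ``id  image  mask  split``
so any DRIVE-/STARE-/CHASE-DB1-style layout can be ingested without
hard-coded paths. Coordinates are row-major, origin top-left; a
translation (dx, dy) moves content right and down, 0-based.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .exceptions import AugmentationError, InputError, SplitError

__all__ = [
    "SamplePair",
    "SplitScheme",
    "load_pair",
    "read_manifest",
    "write_manifest",
    "load_catalog",
    "make_splits",
    "augment",
    "drive_augmentation_grid",
    "write_mask_png",
]

_FLIPS = ("none", "h", "v", "hv")


@dataclass
class SamplePair:
    """One fundus image with its binary expert vessel mask."""

    id: str
    image: np.ndarray  # (H, W, 3) uint8
    mask: np.ndarray   # (H, W) uint8 in {0, 1}, vessel = 1
    pathology: bool | None = None

    def __post_init__(self):
        if self.image.shape[:2] != self.mask.shape:
            raise InputError(
                f"{self.id}: image {self.image.shape[:2]} and mask "
                f"{self.mask.shape} spatial dims differ")
        if not np.isin(self.mask, (0, 1)).all():
            raise InputError(f"{self.id}: mask values must be 0/1")

    @property
    def n_pixels(self) -> int:
        return int(self.mask.size)


@dataclass
class SplitScheme:
    """Train/test assignments for one of the three experiment designs:
    provider-defined fixed split, leave-one-out, or two-fold with halves
    swapped."""

    kind: str
    experiments: list[tuple[list[str], list[str]]]


def _to_gray(arr: np.ndarray) -> np.ndarray:
    if arr.ndim == 4:  # animated formats (GIF) decode as frame stacks
        arr = arr[0]
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr


def _to_rgb(arr: np.ndarray) -> np.ndarray:
    if arr.ndim == 4:
        arr = arr[0]
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[-1] == 4:
        arr = arr[..., :3]
    return arr


def load_pair(image_path, mask_path, binarize_threshold: int = 128,
              sample_id: str | None = None) -> SamplePair:
    """Read an image/mask pair; grayscale mask values >= threshold map to
    vessel (1). Raises InputError with the offending path on failure."""
    try:
        img = _to_rgb(np.asarray(iio.imread(image_path)))
    except Exception as exc:  # noqa: BLE001 - annotate with path
        raise InputError(f"cannot read image {image_path}: {exc}") from exc
    try:
        msk = _to_gray(np.asarray(iio.imread(mask_path)))
    except Exception as exc:  # noqa: BLE001
        raise InputError(f"cannot read mask {mask_path}: {exc}") from exc
    if img.shape[:2] != msk.shape:
        raise InputError(
            f"dimension mismatch: image {image_path} is {img.shape[:2]}, "
            f"mask {mask_path} is {msk.shape}")
    mask = (msk.astype(np.int64) >= binarize_threshold).astype(np.uint8)
    return SamplePair(id=sample_id or Path(image_path).stem,
                      image=img.astype(np.uint8), mask=mask)


def write_mask_png(mask: np.ndarray, path) -> None:
    """Write a binary mask as 8-bit PNG with vessel=255, background=0."""
    iio.imwrite(path, (np.asarray(mask, dtype=np.uint8) * 255))


# -- manifests ----------------------------------------------------------------

_MANIFEST_FIELDS = ["id", "image", "mask", "split"]


def write_manifest(rows: list[dict], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=_MANIFEST_FIELDS, delimiter="\t")
        writer.writeheader()
        for row in rows:
            writer.writerow({k: row.get(k, "") for k in _MANIFEST_FIELDS})


def read_manifest(path) -> list[dict]:
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or [f.strip() for f in reader.fieldnames] != _MANIFEST_FIELDS:
            raise InputError(
                f"manifest {path} must have header {' '.join(_MANIFEST_FIELDS)}")
        return list(reader)


def load_catalog(manifest_path, binarize_threshold: int = 128):
    """Load every pair referenced by a manifest. Relative paths resolve
    against the manifest's directory. Returns (pairs, split_tags)."""
    base = Path(manifest_path).parent
    pairs, tags = [], {}
    for row in read_manifest(manifest_path):
        img = base / row["image"] if not Path(row["image"]).is_absolute() else Path(row["image"])
        msk = base / row["mask"] if not Path(row["mask"]).is_absolute() else Path(row["mask"])
        pairs.append(load_pair(img, msk, binarize_threshold, sample_id=row["id"]))
        tags[row["id"]] = row.get("split", "")
    return pairs, tags


# -- splits -------------------------------------------------------------------

def make_splits(ids, kind: str, split_tags: dict | None = None) -> SplitScheme:
    """Realize one of the three experiment designs over catalog ``ids``.

    fixed: one experiment using provider split tags ('train'/'test');
    leave_one_out: N experiments, each holding out one sample;
    two_fold: 2 experiments over the two halves, swapped.
    """
    ids = list(ids)
    if not ids:
        raise SplitError("empty catalog")
    if kind == "fixed":
        if not split_tags:
            raise SplitError("fixed split requires provider split tags")
        train = [i for i in ids if split_tags.get(i) == "train"]
        test = [i for i in ids if split_tags.get(i) == "test"]
        if set(train) | set(test) != set(ids):
            raise SplitError("fixed split tags must cover the catalog with train/test")
        experiments = [(train, test)]
    elif kind == "leave_one_out":
        if len(ids) < 2:
            raise SplitError("leave-one-out needs >= 2 samples (train set would be empty)")
        experiments = [([j for j in ids if j != i], [i]) for i in ids]
    elif kind == "two_fold":
        if len(ids) % 2 or len(ids) < 2:
            raise SplitError(f"two-fold split needs an even catalog size, got {len(ids)}")
        half = len(ids) // 2
        a, b = ids[:half], ids[half:]
        experiments = [(a, b), (b, a)]
    else:
        raise SplitError(f"unknown split kind {kind!r}")
    return SplitScheme(kind=kind, experiments=experiments)


# -- augmentation -------------------------------------------------------------

def _flip(arr, mode):
    if mode == "none":
        return arr
    if mode == "h":
        return arr[:, ::-1]
    if mode == "v":
        return arr[::-1]
    if mode == "hv":
        return arr[::-1, ::-1]
    raise AugmentationError(f"unknown flip {mode!r}")


def _translate(arr, dx, dy, fill=0):
    out = np.full_like(arr, fill)
    h, w = arr.shape[:2]
    ys = slice(max(dy, 0), min(h, h + dy))
    xs = slice(max(dx, 0), min(w, w + dx))
    ys_src = slice(max(-dy, 0), min(h, h - dy))
    xs_src = slice(max(-dx, 0), min(w, w - dx))
    out[ys, xs] = arr[ys_src, xs_src]
    return out


def drive_augmentation_grid() -> dict:
    """Flip x translation grid expanding each image 192-fold (20 -> 3840).

    4 flip variants x 48 translations: the 7x7 offset lattice
    {-15,...,15 step 5}^2 minus the (15,15) corner, identity included.
    This is a reconstruction of the published image counts, not a
    published grid.
    """
    offsets = [-15, -10, -5, 0, 5, 10, 15]
    translations = [(dx, dy) for dy in offsets for dx in offsets if (dx, dy) != (15, 15)]
    return {"flips": list(_FLIPS), "translations": translations}


def augment(pairs, flips=("none",), translations=((0, 0),), image_fill=0):
    """Deterministic flip/translation product augmentation.

    Image and mask receive identical transforms; translations fill vacated
    pixels with background (0 in the mask, ``image_fill`` — the black
    fundus border — in the image). Output count =
    len(pairs) * len(flips) * len(translations).
    """
    for f in flips:
        if f not in _FLIPS:
            raise AugmentationError(f"unknown flip {f!r}")
    out = []
    for pair in pairs:
        h, w = pair.mask.shape
        for dx, dy in translations:
            if abs(dx) > 0.25 * w or abs(dy) > 0.25 * h:
                raise AugmentationError(
                    f"translation ({dx},{dy}) exceeds 25% of dims ({w},{h})")
        for f in flips:
            fi, fm = _flip(pair.image, f), _flip(pair.mask, f)
            for dx, dy in translations:
                if (f, dx, dy) == ("none", 0, 0):
                    out.append(pair)
                    continue
                out.append(SamplePair(
                    id=f"{pair.id}~{f}~{dx:+d}{dy:+d}",
                    image=np.ascontiguousarray(_translate(fi, dx, dy, image_fill)),
                    mask=np.ascontiguousarray(_translate(fm, dx, dy, 0)),
                    pathology=pair.pathology))
    return out
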