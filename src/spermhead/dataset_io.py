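"""Labeled sperm-head image datasets and their pre-processing.

Datasets are directories of 8-bit PNG/TIFF single-head crops with an
optional CSV manifest (``path,class_name,split``, paths relative to the
manifest).  Pre-processing follows the classification pipeline: scale
intensities to [0, 1], rotate every head to a canonical orientation
(second-moment major axis vertical, heavier end down), replicate
greyscale to three channels, and optionally center-crop on the head
centroid (used for the 131-px high-resolution dataset, cropped to 90).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.filters import threshold_otsu
from skimage.transform import rotate as _sk_rotate

__all__ = [
    "ImageRecord", "LabeledDataset", "load_dataset", "save_dataset",
    "to_three_channels", "normalize_orientation", "center_crop",
    "foreground_mask", "DegenerateInputError",
]


class DegenerateInputError(ValueError):
    """Raised when an image has no usable foreground."""


@dataclass
class ImageRecord:
    """One labeled head image; ``pixels`` is H×W or H×W×3 in [0, 1]."""

    id: str
    pixels: np.ndarray
    class_name: str
    source_path: Path | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim not in (2, 3) or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("pixels must be H×W or H×W×3 with H, W >= 1")
        if px.min() < 0 or px.max() > 1:
            raise ValueError("pixel values must lie in [0, 1]")
        self.pixels = px


@dataclass
class LabeledDataset:
    """An ordered collection of records plus the class manifest."""

    records: list[ImageRecord]
    class_names: list[str]
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("record ids must be unique")
        known = set(self.class_names)
        for r in self.records:
            if r.class_name not in known:
                raise ValueError(f"record {r.id} has unknown class {r.class_name!r}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def class_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in self.class_names}
        for r in self.records:
            counts[r.class_name] += 1
        return counts

    def subset(self, ids: set[str] | list[str], provenance: str = "") -> "LabeledDataset":
        wanted = set(ids)
        recs = [r for r in self.records if r.id in wanted]
        return LabeledDataset(recs, list(self.class_names),
                              provenance or self.provenance)

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Stacked (images, labels); all records must share one shape."""
        x = np.stack([r.pixels for r in self.records])
        y = np.array([r.class_name for r in self.records])
        return x, y

    def map_images(self, fn, provenance: str = "") -> "LabeledDataset":
        recs = [ImageRecord(r.id, fn(r.pixels), r.class_name, r.source_path)
                for r in self.records]
        return LabeledDataset(recs, list(self.class_names),
                              provenance or self.provenance)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _read_image(path: Path) -> np.ndarray:
    import imageio.v3 as iio
    try:
        arr = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # noqa: BLE001 - wrap as a format error
        raise ValueError(f"unreadable image file: {path}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    if arr.dtype == np.uint8:
        return arr.astype(np.float64) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(np.float64) / 65535.0
    return np.clip(arr.astype(np.float64), 0.0, 1.0)


def load_dataset(root: str | Path, manifest: str | Path | None = None) -> LabeledDataset:
    """Load a dataset from a manifest CSV or from one subdirectory per class."""
    root = Path(root)
    if not root.exists():
        raise FileNotFoundError(f"dataset root does not exist: {root}")
    records: list[ImageRecord] = []
    declared_order: list[str] | None = None
    if manifest is not None:
        manifest = Path(manifest)
        base = manifest.parent
        declared_order = []
        with open(manifest, newline="") as fh:
            for i, row in enumerate(csv.DictReader(fh)):
                path = base / row["path"]
                if not path.exists():
                    raise FileNotFoundError(
                        f"manifest row {i + 1}: missing image file {path}")
                if row["class_name"] not in declared_order:
                    declared_order.append(row["class_name"])
                records.append(ImageRecord(row["path"], _read_image(path),
                                           row["class_name"], path))
    else:
        for class_dir in sorted(p for p in root.iterdir() if p.is_dir()):
            for img_path in sorted(class_dir.glob("*")):
                if img_path.suffix.lower() not in {".png", ".tif", ".tiff"}:
                    continue
                rec_id = f"{class_dir.name}/{img_path.name}"
                records.append(ImageRecord(rec_id, _read_image(img_path),
                                           class_dir.name, img_path))
    if not records:
        raise ValueError(f"no images found under {root}")
    if declared_order is not None:
        class_names = declared_order
    else:
        class_names = sorted({r.class_name for r in records})
    return LabeledDataset(records, class_names, provenance=str(root))


def save_dataset(dataset: LabeledDataset, root: str | Path) -> Path:
    """Write 8-bit PNGs plus ``manifest.csv``; returns the manifest path."""
    import imageio.v3 as iio
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    manifest = root / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["path", "class_name", "split"])
        for r in dataset.records:
            rel = Path(r.class_name) / (r.id.replace("/", "_") + ".png")
            (root / rel).parent.mkdir(parents=True, exist_ok=True)
            arr = np.round(np.asarray(r.pixels) * 255).astype(np.uint8)
            iio.imwrite(root / rel, arr)
            writer.writerow([str(rel), r.class_name, ""])
    return manifest


# ---------------------------------------------------------------------------
# Pre-processing
# ---------------------------------------------------------------------------

def to_three_channels(image: np.ndarray) -> np.ndarray:
    """Replicate greyscale to H×W×3; pass 3-channel input through."""
    image = np.asarray(image)
    if image.ndim == 2:
        return np.repeat(image[:, :, None], 3, axis=2)
    if image.ndim == 3 and image.shape[2] == 3:
        return image
    raise ValueError(f"expected H×W or H×W×3 image, got shape {image.shape}")


def _grey(image: np.ndarray) -> np.ndarray:
    return image.mean(axis=2) if image.ndim == 3 else image


def foreground_mask(image: np.ndarray) -> np.ndarray:
    """Otsu-threshold the image; the smaller side is taken as the head.

    Stain polarity (bright-on-dark vs dark-on-bright) varies between
    acquisitions, so the head is identified as whichever side of the
    threshold covers less area.
    """
    g = _grey(np.asarray(image, dtype=np.float64))
    if g.max() == g.min():
        raise DegenerateInputError("constant image has no foreground")
    t = threshold_otsu(g)
    bright = g > t
    mask = bright if bright.sum() <= (~bright).sum() else ~bright
    if not mask.any():
        raise DegenerateInputError("empty foreground after thresholding")
    return mask


def _foreground_weights(image: np.ndarray) -> np.ndarray:
    """Soft foreground membership in [0, 1].

    Graded values near the head boundary carry sub-pixel information, so
    moment estimates from these weights are far less discretization-biased
    than from the hard Otsu mask."""
    g = _grey(np.asarray(image, dtype=np.float64))
    if g.max() == g.min():
        raise DegenerateInputError("constant image has no foreground")
    t = threshold_otsu(g)
    bright = g > t
    if bright.sum() <= (~bright).sum():
        return np.clip((g - t) / max(g.max() - t, 1e-12), 0.0, 1.0)
    return np.clip((t - g) / max(t - g.min(), 1e-12), 0.0, 1.0)


def _moment_angle(weights: np.ndarray) -> tuple[float, float]:
    """(axis angle from the x-axis in degrees, anisotropy measure).

    ``weights`` is a soft or binary foreground map."""
    w = np.asarray(weights, dtype=np.float64)
    total = w.sum()
    if total == 0:
        raise DegenerateInputError("empty foreground")
    yy, xx = np.nonzero(w > 0)
    wv = w[yy, xx]
    xc = (wv * xx).sum() / total
    yc = (wv * yy).sum() / total
    dx, dy = xx - xc, yy - yc
    mu20 = (wv * dx * dx).sum() / total
    mu02 = (wv * dy * dy).sum() / total
    mu11 = (wv * dx * dy).sum() / total
    angle = 0.5 * np.degrees(np.arctan2(2 * mu11, mu20 - mu02))
    aniso = np.hypot(mu20 - mu02, 2 * mu11) / max(mu20 + mu02, 1e-12)
    return angle, aniso


def normalize_orientation(image: np.ndarray, aniso_tol: float = 0.05) -> np.ndarray:
    """Rotate so the head's second-moment major axis is vertical.

    The heavier half (larger foreground mass along the axis) ends up at
    the bottom.  A disc-like head (anisotropy below ``aniso_tol``) has
    no defined axis and is returned unchanged.  Bilinear interpolation,
    edge-replication fill.
    """
    image = np.asarray(image, dtype=np.float64)
    angle, aniso = _moment_angle(_foreground_weights(image))
    if aniso < aniso_tol:
        return image.copy()
    # The axis sits at `angle` from the x-axis in the (col, row) frame;
    # skimage's rotate(beta) maps a feature at angle a to a - beta, so
    # rotating by (angle - 90) brings the axis to the vertical.  A couple of
    # refinement passes absorb the residual the interpolation introduces.
    out = image
    for _ in range(3):
        if abs(angle - 90.0) < 0.25 or abs(angle + 90.0) < 0.25:
            break
        delta = angle - (90.0 if angle >= 0 else -90.0)
        out = _sk_rotate(out, delta, order=1, mode="edge", preserve_range=True)
        angle, _ = _moment_angle(_foreground_weights(out))
    out_mask = foreground_mask(out)
    ys, _ = np.nonzero(out_mask)
    yc = ys.mean()
    below = (ys > yc).sum()
    above = (ys < yc).sum()
    if below < above:  # heavier end up -> turn upside down
        out = _sk_rotate(out, 180.0, order=1, mode="edge", preserve_range=True)
    return np.clip(out, 0.0, 1.0)


def center_crop(image: np.ndarray, out_size: int) -> np.ndarray:
    """Crop an ``out_size`` square centered on the head centroid.

    The window is clamped so it never leaves the frame.
    """
    image = np.asarray(image)
    h, w = image.shape[:2]
    if out_size > min(h, w):
        raise ValueError(f"out_size {out_size} exceeds input {h}×{w}")
    if out_size == h and out_size == w:
        return image.copy()
    mask = foreground_mask(image)
    ys, xs = np.nonzero(mask)
    yc, xc = ys.mean(), xs.mean()
    top = int(round(yc - out_size / 2))
    left = int(round(xc - out_size / 2))
    top = min(max(top, 0), h - out_size)
    left = min(max(left, 0), w - out_size)
    return image[top:top + out_size, left:left + out_size].copy()
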