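"""Synthetic sperm-head image generator.

Renders tiny bright head-shaped blobs on a noisy dark background with
the geometric structure of the five morphology classes: Normal (smooth
oval), Tapered (elongated/asymmetric width), Pyriform (pear-shaped neck
constriction), Small (scaled-down oval) and Amorphous (irregular
boundary).  The head outline is a radial polygon

    r(theta) = r_ellipse(theta) * (1 + taper*cos(theta)*sin^2(theta)
               + neck_pinch*max(0, -cos(theta))*sin^2(theta)
               + irregularity*P(theta))

with P a seeded band-limited harmonic perturbation, so the four shape
knobs map one-to-one onto the four abnormal geometries.  The sin^2
factor on the taper term makes it a pure width asymmetry along the
major axis (a bare taper*cos(theta) term is, to first order, just a
translation of the outline and barely changes the shape).  Everything is
driven by a single integer seed: regenerating with the same
configuration yields bit-identical images and manifest.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .dataset_io import ImageRecord, LabeledDataset, foreground_mask, save_dataset

__all__ = [
    "ShapeParams", "ClassDistribution", "SyntheticDatasetConfig",
    "render_head", "generate_dataset", "shape_features",
    "SCIAN_CLASSES", "HUSHEM_CLASSES", "default_class_distributions",
]

SCIAN_CLASSES = ["Normal", "Tapered", "Pyriform", "Amorphous", "Small"]
HUSHEM_CLASSES = ["Normal", "Tapered", "Pyriform", "Amorphous"]


@dataclass
class ShapeParams:
    """Geometric and photometric parameters of one rendered head."""

    class_name: str = "Normal"
    major_axis: float = 17.0      # px, full axis length at scale 1 in a 35-px frame
    minor_axis: float = 11.0
    taper: float = 0.0            # [0,1] width asymmetry along the major axis
    neck_pinch: float = 0.0       # [0,1] pear constriction
    irregularity: float = 0.0     # [0,1] radial boundary perturbation amplitude
    scale: float = 1.0
    orientation: float = 0.0      # degrees in [0, 360)
    intensity_fg: float = 0.75
    intensity_bg: float = 0.15
    noise_sd: float = 0.05
    boundary_seed: int = 0        # seeds the band-limited perturbation P(theta)

    def validate(self) -> None:
        if not (self.major_axis >= self.minor_axis > 0):
            raise ValueError("need major_axis >= minor_axis > 0")
        for name in ("taper", "neck_pinch", "irregularity"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not (0.0 <= self.orientation < 360.0):
            raise ValueError("orientation must lie in [0, 360)")
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        for name in ("intensity_fg", "intensity_bg"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _boundary_perturbation(theta: np.ndarray, seed: int) -> np.ndarray:
    """Band-limited radial perturbation, normalized to max |P| = 1."""
    rng = np.random.default_rng(seed)
    harmonics = np.arange(3, 8)
    amps = rng.uniform(0.3, 1.0, size=harmonics.size)
    phases = rng.uniform(0.0, 2 * np.pi, size=harmonics.size)
    p = sum(a * np.cos(k * theta + ph) for a, k, ph in zip(amps, harmonics, phases))
    return p / np.abs(p).max() if np.abs(p).max() > 0 else p


def render_head(params: ShapeParams, image_size: int,
                noise_rng: np.random.Generator | int | None = None) -> np.ndarray:
    """Render one head, centered, at the requested orientation.

    Returns an ``image_size`` square greyscale image in [0, 1]:
    ``intensity_fg`` inside the radial outline, ``intensity_bg``
    outside, plus clipped additive Gaussian noise of sd ``noise_sd``
    (noise drawn from ``noise_rng``; omit it or pass an int for a
    deterministic render).
    """
    params.validate()
    if image_size < 16:
        raise ValueError("image_size must be >= 16")
    # 3x3 subpixel supersampling: edge pixels get fractional coverage, which
    # keeps the mask's second moments close to the continuous outline's
    ss = 3
    c = (image_size - 1) / 2.0
    grid = (np.arange(image_size * ss) + 0.5) / ss - 0.5
    yy, xx = np.meshgrid(grid, grid, indexing="ij")
    dx, dy = xx - c, yy - c
    phi = np.radians(params.orientation)
    # rotate into the head frame (major axis along u)
    u = dx * np.cos(phi) + dy * np.sin(phi)
    v = -dx * np.sin(phi) + dy * np.cos(phi)
    theta = np.arctan2(v, u)
    rho = np.hypot(u, v)
    a = params.scale * params.major_axis / 2.0
    b = params.scale * params.minor_axis / 2.0
    r_ell = a * b / np.sqrt((b * np.cos(theta)) ** 2 + (a * np.sin(theta)) ** 2)
    sin2 = np.sin(theta) ** 2
    # the 1.5 gain makes a full pinch widen the base by ~60%, a clearly
    # pear-shaped outline rather than a barely visible bulge
    factor = (1.0 + params.taper * np.cos(theta) * sin2
              + 1.5 * params.neck_pinch * np.maximum(0.0, -np.cos(theta)) * sin2)
    if params.irregularity > 0:
        factor = factor + params.irregularity * _boundary_perturbation(
            theta, params.boundary_seed)
    factor = np.clip(factor, 0.2, None)
    coverage = (rho <= r_ell * factor).astype(np.float64)
    coverage = coverage.reshape(image_size, ss, image_size, ss).mean(axis=(1, 3))
    img = params.intensity_bg + (params.intensity_fg - params.intensity_bg) * coverage
    if params.noise_sd > 0:
        if noise_rng is None or isinstance(noise_rng, (int, np.integer)):
            noise_rng = np.random.default_rng(0 if noise_rng is None else int(noise_rng))
        img = img + noise_rng.normal(0.0, params.noise_sd, size=img.shape)
    return np.clip(img, 0.0, 1.0)


@dataclass
class ClassDistribution:
    """Per-class means and spreads for drawing :class:`ShapeParams`.

    Gaussian draws around the mean, truncated back into each
    parameter's valid range; orientation is uniform on [0, 360) so the
    orientation-normalization stage has real work to do.
    """

    mean: ShapeParams
    axis_sd: float = 0.8
    taper_sd: float = 0.04
    pinch_sd: float = 0.05
    irregularity_sd: float = 0.03
    scale_sd: float = 0.05

    def draw(self, rng: np.random.Generator, class_name: str) -> ShapeParams:
        m = self.mean

        def trunc(value: float, sd: float, lo: float, hi: float) -> float:
            return float(np.clip(value + rng.normal(0.0, sd), lo, hi))

        major = trunc(m.major_axis, self.axis_sd, 4.0, np.inf)
        minor = trunc(m.minor_axis, self.axis_sd, 2.0, major)
        return ShapeParams(
            class_name=class_name,
            major_axis=major,
            minor_axis=minor,
            taper=trunc(m.taper, self.taper_sd, 0.0, 1.0),
            neck_pinch=trunc(m.neck_pinch, self.pinch_sd, 0.0, 1.0),
            irregularity=trunc(m.irregularity, self.irregularity_sd, 0.0, 1.0),
            scale=trunc(m.scale, self.scale_sd, 0.1, 3.0),
            orientation=float(rng.uniform(0.0, 360.0)),
            intensity_fg=m.intensity_fg,
            intensity_bg=m.intensity_bg,
            noise_sd=m.noise_sd,
            boundary_seed=int(rng.integers(0, 2 ** 31 - 1)),
        )


def default_class_distributions(image_size: int = 35) -> dict[str, ClassDistribution]:
    """Presets mimicking the qualitative class distinctions.

    Normal: smooth oval; Tapered: strongly asymmetric width (taper
    0.45); Pyriform: pear constriction (pinch 0.5); Small: scaled to
    0.6; Amorphous: large irregular boundary perturbation (0.5).  Axis
    lengths scale with the frame so the same presets serve 35-px and
    131-px renderings.
    """
    s = image_size / 35.0
    base = ShapeParams(major_axis=17.0 * s, minor_axis=11.0 * s, irregularity=0.05)
    return {
        "Normal": ClassDistribution(mean=replace(base, class_name="Normal")),
        "Tapered": ClassDistribution(mean=replace(
            base, class_name="Tapered", taper=0.45,
            major_axis=19.5 * s, minor_axis=9.0 * s)),
        "Pyriform": ClassDistribution(mean=replace(base, class_name="Pyriform", neck_pinch=0.5)),
        "Small": ClassDistribution(mean=replace(base, class_name="Small", scale=0.6)),
        # "no common structure": a large boundary perturbation, every shape
        # knob drawn with a wide spread, and no size constraint (these are
        # the only heads that run large)
        "Amorphous": ClassDistribution(
            mean=replace(base, class_name="Amorphous", irregularity=0.5,
                         taper=0.15, neck_pinch=0.15, scale=1.15),
            irregularity_sd=0.08, taper_sd=0.15, pinch_sd=0.15,
            axis_sd=2.0, scale_sd=0.12),
    }


@dataclass
class SyntheticDatasetConfig:
    image_size: int = 35
    class_counts: dict[str, int] = field(
        default_factory=lambda: {c: 100 for c in SCIAN_CLASSES})
    class_param_distributions: dict[str, ClassDistribution] | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.image_size < 16:
            raise ValueError("image_size must be >= 16")
        if any(v < 0 for v in self.class_counts.values()):
            raise ValueError("class counts must be >= 0")
        dists = self.distributions()
        unknown = set(self.class_counts) - set(dists)
        if unknown:
            raise ValueError(f"no parameter distribution for classes: {sorted(unknown)}")

    def distributions(self) -> dict[str, ClassDistribution]:
        if self.class_param_distributions is not None:
            return self.class_param_distributions
        return default_class_distributions(self.image_size)


def generate_dataset(config: SyntheticDatasetConfig,
                     out_dir=None) -> LabeledDataset:
    """Generate a labeled dataset with exactly ``class_counts`` records.

    Deterministic in ``config.seed``.  If ``out_dir`` is given the
    images are also written as 8-bit PNGs with a CSV manifest.
    """
    config.validate()
    dists = config.distributions()
    rng = np.random.default_rng(config.seed)
    records: list[ImageRecord] = []
    for class_name in config.class_counts:
        dist = dists[class_name]
        for i in range(config.class_counts[class_name]):
            params = dist.draw(rng, class_name)
            img = render_head(params, config.image_size, noise_rng=rng)
            records.append(ImageRecord(f"{class_name}_{i:04d}", img, class_name))
    ds = LabeledDataset(records, [c for c in config.class_counts],
                        provenance=f"synthetic(seed={config.seed})")
    if out_dir is not None:
        save_dataset(ds, out_dir)
    return ds


def shape_features(image: np.ndarray) -> np.ndarray:
    """(area, eccentricity, taper-moment) of the thresholded head.

    Area is the foreground pixel count; eccentricity comes from the
    second central moments; the taper-moment is the normalized third
    moment (skewness) of foreground mass along the major axis, which
    responds to both tapering and pear constriction.
    """
    mask = foreground_mask(image)
    ys, xs = np.nonzero(mask)
    area = float(mask.sum())
    dx, dy = xs - xs.mean(), ys - ys.mean()
    mu20, mu02, mu11 = (dx * dx).mean(), (dy * dy).mean(), (dx * dy).mean()
    common = np.sqrt(max((mu20 - mu02) ** 2 + 4 * mu11 ** 2, 0.0))
    lam1 = (mu20 + mu02 + common) / 2.0
    lam2 = (mu20 + mu02 - common) / 2.0
    ecc = float(np.sqrt(max(1.0 - lam2 / max(lam1, 1e-12), 0.0)))
    ang = 0.5 * np.arctan2(2 * mu11, mu20 - mu02)
    axis = dx * np.cos(ang) + dy * np.sin(ang)
    sd = axis.std()
    taper_moment = float(np.abs((axis ** 3).mean()) / max(sd ** 3, 1e-12))
    return np.array([area, ecc, taper_moment])
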