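"""Class-balancing data augmentation by per-class transform multiplicity.

The transform space is the grid of integer rotations in [-r, +r]
degrees crossed with five translations (none / ~6% of the width left,
right, up, down) and two flips (none / vertical): (2r+1) * 5 * 2
members, identity included.  Minority classes keep more transforms per
original than majority classes: with a cap of 110 (the full r = 5
space) the multiplicity of class c is

    m_c = round_half_away(cap * n_min / n_c)

which balances every augmented class size n_c * m_c to within ~10%.
A ``uniform`` mode applies the cap to every class, as used when the
classes are already balanced.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from skimage.transform import rotate as _sk_rotate

from .dataset_io import ImageRecord, LabeledDataset
from .partitioning import round_half_away

__all__ = [
    "Transform", "AugmentationSpace", "AugmentationPlan",
    "balancing_multipliers", "select_transforms", "apply_transform",
    "build_plan", "materialize", "DEFAULT_CAP",
]

DEFAULT_CAP = 110
TRANSLATIONS = ("none", "left", "right", "up", "down")
FLIPS = ("none", "vertical")


class Transform(NamedTuple):
    rotation_deg: int
    translation: str  # one of TRANSLATIONS
    flip: str         # one of FLIPS


IDENTITY = Transform(0, "none", "none")


@dataclass(frozen=True)
class AugmentationSpace:
    """Integer-degree rotations in [-limit, +limit] x translations x flips."""

    rotation_limit: int = 5
    translation_fraction: float = 0.06

    @property
    def size(self) -> int:
        return (2 * self.rotation_limit + 1) * len(TRANSLATIONS) * len(FLIPS)

    def members(self) -> list[Transform]:
        return [Transform(r, t, f)
                for r in range(-self.rotation_limit, self.rotation_limit + 1)
                for t in TRANSLATIONS for f in FLIPS]

    def shift_px(self, width: int) -> int:
        return round_half_away(self.translation_fraction * width)

    def __contains__(self, t: Transform) -> bool:
        return (abs(t.rotation_deg) <= self.rotation_limit
                and t.translation in TRANSLATIONS and t.flip in FLIPS)


def balancing_multipliers(class_counts: dict[str, int], cap: int = DEFAULT_CAP,
                          uniform: bool = False) -> dict[str, int]:
    """Images kept per original (identity included) for each class."""
    if not class_counts:
        raise ValueError("class_counts must not be empty")
    if cap < 1 or any(n < 1 for n in class_counts.values()):
        raise ValueError("cap and all class counts must be >= 1")
    if uniform:
        return {c: cap for c in class_counts}
    n_min = min(class_counts.values())
    return {c: max(1, round_half_away(cap * n_min / n))
            for c, n in class_counts.items()}


def select_transforms(space: AugmentationSpace, m: int, seed: int = 0) -> list[Transform]:
    """A seeded choice of m distinct transforms, identity always included."""
    if not (1 <= m <= space.size):
        raise ValueError(f"m must lie in [1, {space.size}], got {m}")
    rest = [t for t in space.members() if t != IDENTITY]
    rng = np.random.default_rng(seed)
    picked = rng.choice(len(rest), size=m - 1, replace=False) if m > 1 else []
    return [IDENTITY] + [rest[i] for i in sorted(picked)]


def _translate(image: np.ndarray, direction: str, px: int) -> np.ndarray:
    """Integer shift with edge replication."""
    if direction == "none" or px == 0:
        return image
    pad = [(px, px), (px, px)] + [(0, 0)] * (image.ndim - 2)
    padded = np.pad(image, pad, mode="edge")
    h, w = image.shape[:2]
    offsets = {"left": (px, 2 * px), "right": (px, 0),
               "up": (2 * px, px), "down": (0, px)}
    dy, dx = offsets[direction]
    return padded[dy:dy + h, dx:dx + w]


def apply_transform(image: np.ndarray, transform: Transform,
                    space: AugmentationSpace | None = None) -> np.ndarray:
    """Rotate about the center, translate with edge replication, then flip
    about the horizontal midline.  The identity returns the input bit-exactly."""
    space = space or AugmentationSpace()
    if transform not in space:
        raise ValueError(f"transform {transform} outside the augmentation space")
    image = np.asarray(image)
    out = image
    if transform.rotation_deg != 0:
        out = np.clip(_sk_rotate(out, transform.rotation_deg, order=1,
                                 mode="edge", preserve_range=True), 0.0, 1.0)
    if transform.translation != "none":
        out = _translate(out, transform.translation, space.shift_px(image.shape[1]))
    if transform.flip == "vertical":
        out = out[::-1].copy()
    return out


@dataclass
class AugmentationPlan:
    """The chosen transform subsets and multiplicities for one training set."""

    space: AugmentationSpace
    class_counts: dict[str, int]
    multipliers: dict[str, int]
    selected: dict[str, list[Transform]]
    cap: int = DEFAULT_CAP

    def augmented_counts(self) -> dict[str, int]:
        return {c: self.class_counts[c] * self.multipliers[c] for c in self.class_counts}

    def total(self) -> int:
        return sum(self.augmented_counts().values())


def build_plan(class_counts: dict[str, int], space: AugmentationSpace | None = None,
               cap: int = DEFAULT_CAP, uniform: bool = False,
               seed: int = 0) -> AugmentationPlan:
    """Multipliers plus a seeded per-class transform subset of each size."""
    space = space or AugmentationSpace()
    mult = balancing_multipliers(class_counts, cap=cap, uniform=uniform)
    if max(mult.values()) > space.size:
        raise ValueError("cap exceeds the transform-space size")
    selected = {c: select_transforms(space, m, seed=seed + i)
                for i, (c, m) in enumerate(mult.items())}
    return AugmentationPlan(space=space, class_counts=dict(class_counts),
                            multipliers=mult, selected=selected, cap=cap)


def materialize(train_set: LabeledDataset, plan: AugmentationPlan,
                seed: int = 0) -> LabeledDataset:
    """Expand a training set to its augmented form.

    Every original appears exactly once (the identity transform) and the
    output class sizes are n_c * m_c.  Only ever apply this to training
    records — development and test sets stay un-augmented.
    """
    missing = set(train_set.class_counts()) - set(plan.multipliers)
    if missing:
        raise ValueError(f"plan lacks multipliers for classes: {sorted(missing)}")
    records: list[ImageRecord] = []
    for rec in train_set.records:
        for t in plan.selected[rec.class_name]:
            if t == IDENTITY:
                records.append(rec)
            else:
                rid = f"{rec.id}#r{t.rotation_deg:+d}_{t.translation}_{t.flip}"
                records.append(ImageRecord(rid, apply_transform(rec.pixels, t, plan.space),
                                           rec.class_name, rec.source_path))
    return LabeledDataset(records, list(train_set.class_names),
                          provenance=train_set.provenance + "+augmented")
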