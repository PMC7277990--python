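"""Stratified k-fold partitioning with a fold-1 development carve.

Each class is split into k test folds whose sizes differ by at most
one; which folds receive the +1 remainder records is a seeded choice.
The development set used for checkpoint/hyperparameter selection is
carved per class as round(fraction * class_total) records taken from
the fold-1 training side (rounding half away from zero).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .dataset_io import LabeledDataset

__all__ = ["FoldPlan", "stratified_kfold", "carve_dev_set", "round_half_away"]


def round_half_away(x: float) -> int:
    """Round to nearest integer, ties away from zero (round(2.5) = 3)."""
    return int(np.sign(x) * np.floor(np.abs(x) + 0.5))


@dataclass
class FoldPlan:
    """Assignment of every record to one of k test folds, plus dev ids."""

    k: int
    assignment: dict[str, int]            # record id -> test-fold index, 1..k
    class_of: dict[str, str]              # record id -> class name
    dev_ids: set[str] = field(default_factory=set)
    seed: int = 0

    def test_ids(self, fold: int) -> list[str]:
        return [rid for rid, f in self.assignment.items() if f == fold]

    def train_ids(self, fold: int) -> list[str]:
        """Training records of ``fold``: everything outside its test part,
        minus the dev carve when training against fold 1."""
        out = [rid for rid, f in self.assignment.items() if f != fold]
        if fold == 1 and self.dev_ids:
            out = [rid for rid in out if rid not in self.dev_ids]
        return out

    def class_quotas(self) -> dict[str, list[int]]:
        """Per class, the k test-fold sizes."""
        quotas: dict[str, list[int]] = {}
        for rid, f in self.assignment.items():
            c = self.class_of[rid]
            quotas.setdefault(c, [0] * self.k)[f - 1] += 1
        return quotas

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["record_id", "class_name", "fold", "role"])
            for rid in self.assignment:
                role = "dev" if rid in self.dev_ids else "test"
                w.writerow([rid, self.class_of[rid], self.assignment[rid], role])

    @classmethod
    def from_csv(cls, path: str | Path, k: int | None = None) -> "FoldPlan":
        assignment, class_of, dev_ids = {}, {}, set()
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                assignment[row["record_id"]] = int(row["fold"])
                class_of[row["record_id"]] = row["class_name"]
                if row["role"] == "dev":
                    dev_ids.add(row["record_id"])
        return cls(k=k or max(assignment.values()), assignment=assignment,
                   class_of=class_of, dev_ids=dev_ids)


def stratified_kfold(dataset: LabeledDataset, k: int, seed: int = 0,
                     quotas: dict[str, list[int]] | None = None) -> FoldPlan:
    """Partition every class across k test folds.

    Per class with n records the fold sizes are ceil(n/k) for (n mod k)
    folds and floor(n/k) for the rest; both the record order and which
    folds get the larger share are seeded choices.  ``quotas`` switches
    to fixture mode: explicit per-class per-fold test sizes (must sum
    to the class count) reproduce a published split verbatim.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    counts = dataset.class_counts()
    if any(v < 1 for v in counts.values()):
        empty = [c for c, v in counts.items() if v < 1]
        raise ValueError(f"every class needs at least one record; empty: {empty}")
    rng = np.random.default_rng(seed)
    assignment: dict[str, int] = {}
    class_of: dict[str, str] = {}
    for class_name in dataset.class_names:
        ids = [r.id for r in dataset.records if r.class_name == class_name]
        n = len(ids)
        if quotas is not None:
            sizes = list(quotas[class_name])
            if len(sizes) != k or sum(sizes) != n:
                raise ValueError(
                    f"quotas for {class_name!r} must be {k} sizes summing to {n}")
        else:
            base, rem = divmod(n, k)
            plus_one = set(rng.choice(k, size=rem, replace=False)) if rem else set()
            sizes = [base + (1 if f in plus_one else 0) for f in range(k)]
        order = rng.permutation(n)
        pos = 0
        for fold_idx, size in enumerate(sizes, start=1):
            for j in order[pos:pos + size]:
                assignment[ids[j]] = fold_idx
                class_of[ids[j]] = class_name
            pos += size
    # restore dataset record order for reproducible serialization
    ordered = {r.id: assignment[r.id] for r in dataset.records}
    class_of = {r.id: r.class_name for r in dataset.records}
    return FoldPlan(k=k, assignment=ordered, class_of=class_of, seed=seed)


def carve_dev_set(plan: FoldPlan, dataset: LabeledDataset, fraction: float,
                  seed: int | None = None) -> FoldPlan:
    """Move round(fraction * class_total) records per class from fold-1
    training into the development set."""
    if not (0.0 <= fraction < 1.0):
        raise ValueError("fraction must lie in [0, 1)")
    if plan.dev_ids:
        raise ValueError("plan already has a development set")
    rng = np.random.default_rng(plan.seed if seed is None else seed)
    counts = dataset.class_counts()
    dev_ids: set[str] = set()
    for class_name in dataset.class_names:
        want = round_half_away(fraction * counts[class_name])
        pool = [rid for rid, f in plan.assignment.items()
                if f != 1 and plan.class_of[rid] == class_name]
        if want > len(pool):
            raise ValueError(
                f"dev carve of {want} exceeds fold-1 training size "
                f"{len(pool)} for class {class_name!r}")
        chosen = rng.choice(len(pool), size=want, replace=False) if want else []
        dev_ids.update(pool[i] for i in chosen)
    return FoldPlan(k=plan.k, assignment=dict(plan.assignment),
                    class_of=dict(plan.class_of), dev_ids=dev_ids, seed=plan.seed)
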