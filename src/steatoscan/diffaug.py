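"""Pixel-level differential-image augmentation and the train/test split.

The four steatosis grades fall into two gray-close pairs: {C1, C2} (dark) and
{C3, C4} (bright).  Within each pair, let phi be the grand mean gray value of
all patches in the pair and phi_i the mean of class i.  The differential image
of patch I_j from class i is

    DI_j = I_j - (phi_i - phi)

i.e. every class is re-centred onto the common pair mean.  Algebraically the
two classes of a pair then share the same expected gray level (both equal
phi), which removes the dominant brightness cue *within* a pair and forces a
classifier to rely on texture — while doubling the number of training
examples.  Differential patches keep their parent's label and are used for
training only, never for testing.

Differential values may leave [0, 255]; they are stored as signed floats,
unclipped.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import DegenerateGroupError, LeakageError, ParameterError
from .patches import Patch
from .synth import CLASS_LABELS

DEFAULT_GROUPS: tuple[tuple[str, str], ...] = (("C1", "C2"), ("C3", "C4"))


@dataclass(frozen=True)
class ClassGroup:
    """Two gray-close classes and their patch lists."""

    labels: tuple[str, str]
    patches_1: tuple[Patch, ...]
    patches_2: tuple[Patch, ...]

    @classmethod
    def from_patches(cls, patches: Sequence[Patch], labels: tuple[str, str]) -> "ClassGroup":
        a, b = labels
        return cls(
            labels=labels,
            patches_1=tuple(p for p in patches if p.class_label == a),
            patches_2=tuple(p for p in patches if p.class_label == b),
        )


@dataclass(frozen=True)
class GroupStats:
    """Grand and per-class mean gray values of a two-class group.

    ``phi`` is the mean over all pixels of all patches in the group; ``phi1``
    and ``phi2`` are the per-class pixel means.  Satisfies the weighted-mean
    identity ``n*phi = n1*phi1 + n2*phi2`` (n counted in patches since all
    patches share one size).
    """

    n: int
    n1: int
    n2: int
    phi: float
    phi1: float
    phi2: float


@dataclass(frozen=True)
class DifferentialPatch:
    """A signed, re-centred copy of a parent patch (training-only sample)."""

    pixels: np.ndarray  # signed float, unclipped
    parent_id: str
    class_label: str
    group: tuple[str, str]

    @property
    def patch_id(self) -> str:
        return f"diff_{self.parent_id}"


@dataclass(frozen=True)
class DatasetSplit:
    """Stratified split: train = originals + differentials, test = originals only."""

    train_originals: tuple[Patch, ...]
    train_differentials: tuple[DifferentialPatch, ...]
    test: tuple[Patch, ...]
    train_fraction: float
    seed: int
    diff_fraction: float = 1.0

    def __post_init__(self) -> None:
        train_ids = {p.patch_id for p in self.train_originals}
        test_ids = {p.patch_id for p in self.test}
        overlap = train_ids & test_ids
        if overlap:
            raise LeakageError(f"patches on both sides of the split: {sorted(overlap)[:5]}")
        leaked = [d.patch_id for d in self.train_differentials if d.parent_id in test_ids]
        if leaked:
            raise LeakageError(f"differential parents in the test set: {leaked[:5]}")

    @property
    def train(self) -> tuple[Patch | DifferentialPatch, ...]:
        return self.train_originals + self.train_differentials

    def manifest(self) -> dict:
        return {
            "seed": self.seed,
            "train_fraction": self.train_fraction,
            "diff_fraction": self.diff_fraction,
            "train_originals": [p.patch_id for p in self.train_originals],
            "train_differentials": [d.patch_id for d in self.train_differentials],
            "test": [p.patch_id for p in self.test],
        }

    def save_manifest(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.manifest(), indent=1))


def compute_group_stats(group: ClassGroup) -> GroupStats:
    """Grand mean phi and per-class means phi1/phi2 of a two-class group."""
    if not group.patches_1 or not group.patches_2:
        raise DegenerateGroupError(
            f"group {group.labels} has an empty class "
            f"(n1={len(group.patches_1)}, n2={len(group.patches_2)})"
        )
    pix1 = np.stack([p.pixels for p in group.patches_1]).astype(np.float64)
    pix2 = np.stack([p.pixels for p in group.patches_2]).astype(np.float64)
    phi1 = float(pix1.mean())
    phi2 = float(pix2.mean())
    n1, n2 = len(group.patches_1), len(group.patches_2)
    # all patches share one window size, so the pixel grand mean is the
    # patch-count-weighted mean of the class means
    phi = (n1 * phi1 * pix1[0].size + n2 * phi2 * pix2[0].size) / (
        n1 * pix1[0].size + n2 * pix2[0].size
    )
    return GroupStats(n=n1 + n2, n1=n1, n2=n2, phi=float(phi), phi1=phi1, phi2=phi2)


def compute_differential_patches(
    group: ClassGroup,
    stats: GroupStats | None = None,
    fraction: float = 0.5,
    seed: int = 0,
    pixelwise: bool = False,
) -> list[DifferentialPatch]:
    """Emit DI_j = I_j - (phi_i - phi) for a seeded per-class sample of patches.

    ``fraction`` in (0, 1] selects the share of each class's patches to
    transform (uniformly at random, seeded).  After the transformation the
    expected pixel mean of each class's differentials equals phi.

    With ``pixelwise=True`` the scalar means are replaced by per-pixel mean
    images (the offset becomes a w x w map), aligning every pixel position's
    class mean with the group's; the default scalar form matches the grand
    gray-mean bookkeeping of :class:`GroupStats`.
    """
    if not 0.0 < fraction <= 1.0:
        raise ParameterError(f"fraction must be in (0, 1], got {fraction}")
    if stats is None:
        stats = compute_group_stats(group)

    if pixelwise:
        pix1 = np.stack([p.pixels for p in group.patches_1]).astype(np.float64)
        pix2 = np.stack([p.pixels for p in group.patches_2]).astype(np.float64)
        phi_map = np.concatenate([pix1, pix2]).mean(axis=0)
        offsets = (pix1.mean(axis=0) - phi_map, pix2.mean(axis=0) - phi_map)
    else:
        offsets = (stats.phi1 - stats.phi, stats.phi2 - stats.phi)

    rng = np.random.default_rng(seed)
    out: list[DifferentialPatch] = []
    for class_patches, offset in zip((group.patches_1, group.patches_2), offsets):
        n_take = max(1, int(round(fraction * len(class_patches))))
        idx = np.sort(rng.choice(len(class_patches), size=n_take, replace=False))
        for i in idx:
            parent = class_patches[i]
            out.append(
                DifferentialPatch(
                    pixels=parent.pixels.astype(np.float64) - offset,
                    parent_id=parent.patch_id,
                    class_label=parent.class_label,
                    group=group.labels,
                )
            )
    return out


def build_split(
    patches: Sequence[Patch],
    train_fraction: float = 0.5,
    seed: int = 0,
    diff_fraction: float = 1.0,
    groups: Sequence[tuple[str, str]] = DEFAULT_GROUPS,
) -> DatasetSplit:
    """Stratified seeded split with leakage-free differential augmentation.

    The original patches are first split per class (train_fraction to train,
    remainder to test); group statistics and differentials are then computed
    from the train side only, so no information from test patches enters
    training.  With ``diff_fraction = 1.0`` every train-side patch also
    contributes a differential, giving the 50% originals + equally many
    differentials training composition.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ParameterError(f"train_fraction must be in (0, 1), got {train_fraction}")

    rng = np.random.default_rng(seed)
    train: list[Patch] = []
    test: list[Patch] = []
    labels = sorted({p.class_label for p in patches}, key=CLASS_LABELS.index)
    for c in labels:
        pool = [p for p in patches if p.class_label == c]
        perm = rng.permutation(len(pool))
        n_train = int(round(train_fraction * len(pool)))
        n_train = min(max(n_train, 1), len(pool) - 1)  # keep both sides non-empty
        train.extend(pool[i] for i in perm[:n_train])
        test.extend(pool[i] for i in perm[n_train:])

    differentials: list[DifferentialPatch] = []
    for g in groups:
        grp = ClassGroup.from_patches(train, tuple(g))
        if not grp.patches_1 or not grp.patches_2:
            continue
        stats = compute_group_stats(grp)
        differentials.extend(
            compute_differential_patches(grp, stats, fraction=diff_fraction, seed=seed)
        )

    return DatasetSplit(
        train_originals=tuple(train),
        train_differentials=tuple(differentials),
        test=tuple(test),
        train_fraction=train_fraction,
        seed=seed,
        diff_fraction=diff_fraction,
    )


def write_differentials(
    differentials: Sequence[DifferentialPatch], out_dir: str | Path
) -> Path:
    """Write signed differential patches as .npy files plus ``diff.csv``."""
    import csv

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    csv_path = out / "diff.csv"
    with open(csv_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["diff_id", "parent_id", "class", "group", "path"])
        for d in differentials:
            fname = f"{d.patch_id}.npy"
            np.save(out / fname, d.pixels)
            writer.writerow([d.patch_id, d.parent_id, d.class_label, "+".join(d.group), fname])
    return csv_path
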