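"""Per-nucleus Dice overlap across sessions and raters.

Inputs must already share a voxel grid: no registration or resampling
happens here (hidden nearest-neighbour resampling would corrupt overlap
values), so co-register label maps upstream and bring them onto one grid.

Conventions: Dice(A, B) = 2|A∩B| / (|A| + |B|); when both masks are empty
the structures agree on absence and Dice is 1.0, when exactly one is empty
Dice is 0.0. This convention is recorded in every report's metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .dwi_io import LabelMap
from .errors import GeometryError, ValidationError

__all__ = [
    "dice",
    "multilabel_dice",
    "pairwise_report",
    "perturb_labels",
    "DiceReport",
]

_EMPTY_CONVENTION = "both-empty dice = 1.0; one-empty dice = 0.0"


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice coefficient of two boolean masks of identical shape."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise GeometryError(f"mask shapes differ: {a.shape} vs {b.shape}")
    na = int(a.sum())
    nb = int(b.sum())
    if na + nb == 0:
        return 1.0
    inter = int(np.count_nonzero(a & b))
    return 2.0 * inter / (na + nb)


def _check_geometry(a: LabelMap, b: LabelMap) -> None:
    if a.labels.shape != b.labels.shape:
        raise GeometryError(
            f"label volumes differ in shape ({a.labels.shape} vs "
            f"{b.labels.shape}); inputs must be co-registered onto one grid "
            "before computing overlap"
        )
    if not np.allclose(a.affine, b.affine, atol=1e-4):
        raise GeometryError(
            "label volumes differ in affine; inputs must be co-registered "
            "onto one grid before computing overlap"
        )


def multilabel_dice(a: LabelMap, b: LabelMap) -> pd.DataFrame:
    """Per-label Dice over the union of nonzero labels in either map.

    Returns one row per label with columns
    ``label, name, dice, voxels_a, voxels_b``.
    """
    _check_geometry(a, b)
    union = sorted(set(a.present_labels().tolist()) | set(b.present_labels().tolist()))
    rows = []
    for lab in union:
        ma = a.labels == lab
        mb = b.labels == lab
        rows.append(
            {
                "label": int(lab),
                "name": a.names.get(lab, b.names.get(lab, f"label_{lab}")),
                "dice": dice(ma, mb),
                "voxels_a": int(ma.sum()),
                "voxels_b": int(mb.sum()),
            }
        )
    return pd.DataFrame(rows, columns=["label", "name", "dice", "voxels_a", "voxels_b"])


@dataclass
class DiceReport:
    """All-pairs Dice records plus per-label summary statistics."""

    records: pd.DataFrame
    summary: pd.DataFrame
    metadata: dict = field(default_factory=dict)


def pairwise_report(
    maps: list[LabelMap], ids: list[str] | None = None
) -> DiceReport:
    """Evaluate every unordered pair of k co-registered label maps.

    With every label present in every map this yields C(k, 2) comparisons
    per label — e.g. 28 for an 8-scan test-retest design and 3 for a
    three-rater design. Pairs in which neither map contains a label are
    skipped (they would contribute only trivial agreement-on-absence).
    Records are sorted by label, then identifier pair.
    """
    if len(maps) < 2:
        raise ValidationError("need at least 2 label maps to compare")
    if ids is None:
        ids = [f"map{i}" for i in range(len(maps))]
    if len(ids) != len(maps):
        raise ValidationError("one identifier per map required")
    for m in maps[1:]:
        _check_geometry(maps[0], m)

    rows = []
    for (ia, ma), (ib, mb) in combinations(zip(ids, maps), 2):
        df = multilabel_dice(ma, mb)
        df = df[(df["voxels_a"] > 0) | (df["voxels_b"] > 0)]
        for _, r in df.iterrows():
            rows.append(
                {
                    "label": int(r["label"]),
                    "name": r["name"],
                    "id_a": ia,
                    "id_b": ib,
                    "dice": float(r["dice"]),
                    "voxels_a": int(r["voxels_a"]),
                    "voxels_b": int(r["voxels_b"]),
                }
            )
    records = pd.DataFrame(
        rows,
        columns=["label", "name", "id_a", "id_b", "dice", "voxels_a", "voxels_b"],
    ).sort_values(["label", "id_a", "id_b"], ignore_index=True)

    summary = (
        records.groupby(["label", "name"], as_index=False)
        .agg(mean_dice=("dice", "mean"), sd_dice=("dice", "std"), n=("dice", "size"))
        .sort_values("label", ignore_index=True)
    )
    summary["sd_dice"] = summary["sd_dice"].fillna(0.0)
    return DiceReport(
        records=records,
        summary=summary,
        metadata={"n_maps": len(maps), "empty_mask_convention": _EMPTY_CONVENTION},
    )


# --------------------------------------------------------------------------
# synthetic rater variability

_OFFSETS = np.array(
    [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
)


def perturb_labels(labelmap: LabelMap, boundary_flip_rate: float, seed: int) -> LabelMap:
    """Randomly reassign foreground boundary voxels to a neighboring label.

    A boundary voxel is a nonzero voxel with at least one 6-connected
    neighbor carrying a different label (the volume edge counts as
    background). Each boundary voxel is independently flipped with
    probability ``boundary_flip_rate`` to a label drawn uniformly from the
    distinct differing neighbor labels (background included). All flips are
    decided against the original map, so the result does not depend on
    traversal order; fixed seed, fixed output.
    """
    if not 0.0 <= boundary_flip_rate <= 1.0:
        raise ValidationError("boundary_flip_rate must be in [0, 1]")
    labels = labelmap.labels
    padded = np.pad(labels, 1, mode="constant", constant_values=0)

    # neighbor values along the 6 faces, shape (6, *shape)
    core = (slice(1, -1),) * 3
    neighbors = np.stack(
        [
            padded[tuple(slice(1 + o, s + 1 + o) for o, s in zip(off, labels.shape))]
            for off in _OFFSETS
        ]
    )
    differs = neighbors != labels[None]
    boundary = (labels > 0) & differs.any(axis=0)
    del core

    out = labels.copy()
    if boundary_flip_rate == 0.0 or not boundary.any():
        return LabelMap(out, labelmap.affine.copy(), dict(labelmap.names))

    rng = np.random.default_rng(seed)
    coords = np.argwhere(boundary)
    flip = rng.random(len(coords)) < boundary_flip_rate
    for (i, j, k) in coords[flip]:
        own = labels[i, j, k]
        cand = np.unique(neighbors[:, i, j, k])
        cand = cand[cand != own]
        out[i, j, k] = rng.choice(cand)
    return LabelMap(out, labelmap.affine.copy(), dict(labelmap.names))
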