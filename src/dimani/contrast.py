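"""The DiMANI contrast: voxelwise aggregation of b-thresholded
diffusion-weighted volumes.

Averaging the weighted volumes of a diffusion acquisition produces a
trace-like ("isotropic DWI") image in which freely/isotropically diffusing
tissue (CSF) is dark and restricted or anisotropic tissue (white matter,
densely myelinated laminae) is bright — enough intra-thalamic contrast to
delineate individual subnuclei. Five aggregation variants are provided
(mean, median, centromean, sum, l2norm); they differ in voxel values but
carry essentially the same spatial contrast.

For display, a 3D contrast-limited adaptive histogram equalization (CLAHE)
is provided with optional foreground masking: per-tile histograms are
clipped at a fraction of the tile's voxel count, the excess is redistributed
uniformly, and the per-tile CDF mappings are blended by trilinear
interpolation between tile centers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dwi_io import DWIDataset, LabelMap
from .errors import GeometryError, ValidationError

__all__ = [
    "AGGREGATION_METHODS",
    "ContrastImage",
    "select_weighted",
    "select_b0",
    "compute_contrast",
    "b0_mean",
    "equalize_adaptive",
    "region_stats",
]

AGGREGATION_METHODS = ("mean", "median", "centromean", "sum", "l2norm")

#: default b-value cut for "diffusion weighted": keep volumes with b > 100 s/mm^2
DEFAULT_B_THRESHOLD = 100.0


@dataclass
class ContrastImage:
    """A 3D DiMANI image together with how it was produced."""

    values: np.ndarray
    affine: np.ndarray
    method: str
    b_threshold: float = DEFAULT_B_THRESHOLD
    shell: float | None = None
    equalized: bool = False
    equalize_params: dict | None = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.values.ndim != 3:
            raise ValidationError("contrast values must be a 3D volume")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("contrast values must be finite")
        if self.equalized:
            if self.values.min() < 0 or self.values.max() > 1:
                raise ValidationError("equalized values must lie in [0, 1]")
        elif self.values.min() < 0:
            raise ValidationError("raw contrast values must be non-negative")

    def provenance(self) -> dict:
        """JSON-serializable record of how this image was computed."""
        return {
            "method": self.method,
            "b_threshold": self.b_threshold,
            "shell": self.shell,
            "equalized": self.equalized,
            "equalize_params": self.equalize_params,
        }


# --------------------------------------------------------------------------
# volume selection


def select_weighted(
    ds: DWIDataset,
    b_threshold: float = DEFAULT_B_THRESHOLD,
    shell: float | None = None,
    shell_tolerance: float = 50.0,
) -> np.ndarray:
    """Indices of the diffusion-weighted volumes (strictly b > b_threshold).

    With ``shell`` given, additionally restrict to |b - shell| <= tolerance,
    reproducing single-shell use on multi-shell acquisitions. Order of the
    original 4D axis is preserved.
    """
    if b_threshold < 0:
        raise ValidationError("b_threshold must be >= 0")
    bvals = ds.gradients.bvals
    keep = bvals > b_threshold
    if shell is not None:
        if shell <= b_threshold:
            raise ValidationError("shell must exceed b_threshold")
        keep &= np.abs(bvals - shell) <= shell_tolerance
    idx = np.flatnonzero(keep)
    if idx.size == 0:
        msg = f"no volumes with b > {b_threshold}"
        if shell is not None:
            msg += f" within {shell_tolerance} of shell {shell}"
        raise ValidationError(msg + f"; available b-values: {np.unique(bvals).tolist()}")
    return idx


def select_b0(ds: DWIDataset, b_threshold: float = DEFAULT_B_THRESHOLD) -> np.ndarray:
    """Indices of the (nominal) b0 volumes: b <= b_threshold."""
    idx = np.flatnonzero(ds.gradients.bvals <= b_threshold)
    if idx.size == 0:
        raise ValidationError(
            f"no volumes with b <= {b_threshold}; available b-values: "
            f"{np.unique(ds.gradients.bvals).tolist()}"
        )
    return idx


# --------------------------------------------------------------------------
# aggregation


def _centromean(stack: np.ndarray) -> np.ndarray:
    # mean of the middle ~50%: drop floor(n/4) lowest and highest per voxel
    n = stack.shape[-1]
    k = n // 4
    return stack[..., k : n - k].mean(axis=-1)


_AGGREGATORS = {
    "mean": lambda s: s.mean(axis=-1),
    "median": lambda s: np.median(s, axis=-1),
    "centromean": _centromean,
    "sum": lambda s: s.sum(axis=-1),
    "l2norm": lambda s: np.sqrt(np.sum(s * s, axis=-1)),
}


def compute_contrast(
    ds: DWIDataset,
    method: str = "mean",
    b_threshold: float = DEFAULT_B_THRESHOLD,
    shell: float | None = None,
    shell_tolerance: float = 50.0,
    mask: np.ndarray | None = None,
) -> ContrastImage:
    """Aggregate the selected diffusion-weighted volumes voxelwise.

    ``method`` is one of :data:`AGGREGATION_METHODS`. With a boolean ``mask``,
    voxels outside it are set to 0. The result is deterministic and
    independent of volume ordering.
    """
    if method not in _AGGREGATORS:
        raise ValidationError(
            f"unknown aggregation method {method!r}; choose from {AGGREGATION_METHODS}"
        )
    idx = select_weighted(ds, b_threshold, shell, shell_tolerance)
    # sort per voxel so the reduction order is canonical: the result is then
    # bit-identical under any permutation of the input volumes
    values = _AGGREGATORS[method](np.sort(ds.signal[..., idx], axis=-1))
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != ds.spatial_shape:
            raise GeometryError(
                f"mask shape {mask.shape} does not match volume {ds.spatial_shape}"
            )
        values = np.where(mask, values, 0.0)
    return ContrastImage(
        values=values,
        affine=ds.affine,
        method=method,
        b_threshold=b_threshold,
        shell=shell,
    )


def b0_mean(ds: DWIDataset, b_threshold: float = DEFAULT_B_THRESHOLD) -> ContrastImage:
    """Mean of the b0 volumes (the companion non-weighted average image)."""
    idx = select_b0(ds, b_threshold)
    return ContrastImage(
        values=ds.signal[..., idx].mean(axis=-1),
        affine=ds.affine,
        method="b0_mean",
        b_threshold=b_threshold,
    )


# --------------------------------------------------------------------------
# adaptive histogram equalization (3D CLAHE with optional mask)


def _default_kernel(shape: tuple[int, ...]) -> tuple[int, ...]:
    return tuple(max(4, s // 8) for s in shape)


def _tile_edges(extent: int, kernel: int) -> np.ndarray:
    n_tiles = max(1, int(np.ceil(extent / kernel)))
    return np.round(np.linspace(0, extent, n_tiles + 1)).astype(int)


def _clahe3d(
    values: np.ndarray,
    kernel_shape: tuple[int, int, int],
    clip_limit: float,
    n_bins: int,
    mask: np.ndarray | None,
) -> np.ndarray:
    sel = np.ones(values.shape, bool) if mask is None else mask
    vmin = float(values[sel].min())
    vmax = float(values[sel].max())
    if vmax == vmin:
        warnings.warn("degenerate dynamic range (max == min): returning all zeros")
        return np.zeros_like(values, dtype=float)

    norm = np.clip((values - vmin) / (vmax - vmin), 0.0, 1.0)
    bins = np.minimum((norm * n_bins).astype(np.int64), n_bins - 1)

    edges = [_tile_edges(s, k) for s, k in zip(values.shape, kernel_shape)]
    n_tiles = [len(e) - 1 for e in edges]
    centers = [(e[:-1] + e[1:] - 1) / 2.0 for e in edges]

    # per-tile clipped-histogram CDF mappings
    identity = (np.arange(n_bins) + 0.5) / n_bins  # for tiles with no foreground
    mappings = np.empty((*n_tiles, n_bins))
    for i in range(n_tiles[0]):
        for j in range(n_tiles[1]):
            for k in range(n_tiles[2]):
                sl = (
                    slice(edges[0][i], edges[0][i + 1]),
                    slice(edges[1][j], edges[1][j + 1]),
                    slice(edges[2][k], edges[2][k + 1]),
                )
                tb = bins[sl][sel[sl]]
                if tb.size == 0:
                    mappings[i, j, k] = identity
                    continue
                hist = np.bincount(tb, minlength=n_bins).astype(float)
                clip = max(clip_limit * tb.size, 1.0)
                excess = np.sum(np.maximum(hist - clip, 0.0))
                hist = np.minimum(hist, clip)
                hist += excess / n_bins
                mappings[i, j, k] = np.cumsum(hist) / hist.sum()

    # trilinear blend of the tile mappings, clamped at the volume edges
    lows, fracs = [], []
    for ax in range(3):
        coord = np.arange(values.shape[ax], dtype=float)
        c = centers[ax]
        if len(c) == 1:
            lows.append(np.zeros(len(coord), dtype=int))
            fracs.append(np.zeros(len(coord)))
            continue
        lo = np.clip(np.searchsorted(c, coord, side="right") - 1, 0, len(c) - 2)
        f = np.clip((coord - c[lo]) / (c[lo + 1] - c[lo]), 0.0, 1.0)
        lows.append(lo)
        fracs.append(f)

    out = np.zeros(values.shape)
    for a in (0, 1):
        wx = (fracs[0] if a else 1 - fracs[0])[:, None, None]
        ix = np.minimum(lows[0] + a, n_tiles[0] - 1)[:, None, None]
        for b in (0, 1):
            wy = (fracs[1] if b else 1 - fracs[1])[None, :, None]
            iy = np.minimum(lows[1] + b, n_tiles[1] - 1)[None, :, None]
            for c in (0, 1):
                wz = (fracs[2] if c else 1 - fracs[2])[None, None, :]
                iz = np.minimum(lows[2] + c, n_tiles[2] - 1)[None, None, :]
                out += (wx * wy * wz) * mappings[ix, iy, iz, bins]

    if mask is not None:
        out = np.where(mask, out, 0.0)
    return np.clip(out, 0.0, 1.0)


def equalize_adaptive(
    image: ContrastImage,
    kernel_shape: tuple[int, int, int] | None = None,
    clip_limit: float = 0.01,
    n_bins: int = 256,
    mask: np.ndarray | None = None,
) -> ContrastImage:
    """Contrast-limited adaptive histogram equalization of a DiMANI image.

    Parameters
    ----------
    kernel_shape:
        tile size per axis in voxels; default ``shape // 8`` (min 4),
        clipped to the image extent.
    clip_limit:
        histogram clip as a fraction of each tile's voxel count, in (0, 1].
        1.0 disables clipping (plain adaptive equalization).
    n_bins:
        histogram resolution (>= 2).
    mask:
        optional boolean foreground; only masked voxels enter the histograms
        and the background stays exactly 0 in the output.

    Returns a new image with values in [0, 1], ``equalized=True`` and the
    parameters recorded. A constant input yields an all-zero image with a
    warning rather than an error.
    """
    if image.equalized:
        raise ValidationError("image is already equalized")
    shape = image.values.shape
    if kernel_shape is None:
        kernel_shape = _default_kernel(shape)
    kernel_shape = tuple(int(k) for k in kernel_shape)
    if len(kernel_shape) != 3 or any(k < 1 for k in kernel_shape):
        raise ValidationError("kernel_shape must be three positive integers")
    if any(k > s for k, s in zip(kernel_shape, shape)):
        raise ValidationError(
            f"kernel_shape {kernel_shape} exceeds image shape {shape}"
        )
    if not (0 < clip_limit <= 1):
        raise ValidationError("clip_limit must be in (0, 1]")
    if n_bins < 2:
        raise ValidationError("n_bins must be >= 2")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != shape:
            raise GeometryError("mask shape does not match image")
        if not mask.any():
            raise ValidationError("mask selects no voxels")

    out = _clahe3d(image.values, kernel_shape, clip_limit, n_bins, mask)
    return replace(
        image,
        values=out,
        equalized=True,
        equalize_params={
            "kernel_shape": list(kernel_shape),
            "clip_limit": clip_limit,
            "n_bins": n_bins,
            "masked": mask is not None,
        },
    )


# --------------------------------------------------------------------------
# per-region summaries


def region_stats(image: ContrastImage, labels: LabelMap) -> pd.DataFrame:
    """Mean, SD and voxel count of the contrast within each labeled region.

    Image and label map must share grid shape and affine (within 1e-4).
    Returns one row per nonzero label present in the map, sorted by label.
    """
    if image.values.shape != labels.labels.shape:
        raise GeometryError(
            f"image shape {image.values.shape} != labels shape {labels.labels.shape}"
        )
    if not np.allclose(image.affine, labels.affine, atol=1e-4):
        raise GeometryError("image and labels have different affines")
    rows = []
    for lab in labels.present_labels():
        vox = image.values[labels.labels == lab]
        rows.append(
            {
                "label": int(lab),
                "name": labels.names.get(int(lab), f"label_{int(lab)}"),
                "mean": float(vox.mean()),
                "sd": float(vox.std()),
                "n": int(vox.size),
            }
        )
    return pd.DataFrame(rows, columns=["label", "name", "mean", "sd", "n"])
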