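"""Reading and writing the diffusion-MRI file trio (NIfTI + bvals/bvecs)
and multilabel NIfTI segmentations.

Conventions
-----------
* bvals / bvecs follow the FSL dialect: ``bvals`` is one whitespace-separated
  row of numbers; ``bvecs`` is 3 rows by N columns. A transposed N-by-3 bvecs
  file is auto-detected by shape and accepted with a warning, since both
  layouts circulate and a silent misread would be catastrophic.
* bvecs are stored as given (image-coordinate, FSL-style); no world-coordinate
  rotation is applied. The contrast aggregates over directions and is
  insensitive to a global rotation of the scheme.
* Voxel indexing is 0-based; world coordinates follow the NIfTI affine.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import ConsistencyError, ValidationError

__all__ = [
    "GradientTable",
    "DWIDataset",
    "LabelMap",
    "read_dwi",
    "read_labelmap",
    "write_image",
    "write_labelmap",
    "load_names",
]

#: unit-norm tolerance for weighted gradient directions
BVEC_NORM_TOL = 1e-3


@dataclass
class GradientTable:
    """Per-volume b-values (s/mm^2) and unit gradient directions.

    b=0 entries may carry a zero direction vector; every weighted entry
    (b > 0) must be unit-norm within ``BVEC_NORM_TOL``.
    """

    bvals: np.ndarray
    bvecs: np.ndarray

    def __post_init__(self) -> None:
        self.bvals = np.atleast_1d(np.asarray(self.bvals, dtype=float))
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        if self.bvals.ndim != 1:
            raise ValidationError("bvals must be a 1-D sequence")
        if self.bvecs.ndim != 2 or self.bvecs.shape[1] != 3:
            raise ValidationError(
                f"bvecs must have shape (n, 3), got {self.bvecs.shape}"
            )
        if len(self.bvals) != len(self.bvecs):
            raise ConsistencyError(
                f"{len(self.bvals)} b-values but {len(self.bvecs)} directions"
            )
        if np.any(self.bvals < 0):
            raise ValidationError("negative b-values are not physical")
        norms = np.linalg.norm(self.bvecs, axis=1)
        weighted = self.bvals > 0
        bad = weighted & (np.abs(norms - 1.0) > BVEC_NORM_TOL)
        if np.any(bad):
            idx = np.flatnonzero(bad)
            raise ValidationError(
                f"non-unit gradient direction(s) at volume(s) {idx.tolist()} "
                f"(norms {norms[idx].round(4).tolist()}); pass "
                "renormalize_bvecs=True to read_dwi to rescale them"
            )

    @property
    def n_volumes(self) -> int:
        return len(self.bvals)

    def renormalized(self) -> "GradientTable":
        """Return a copy with every nonzero direction rescaled to unit norm."""
        vecs = self.bvecs.copy()
        norms = np.linalg.norm(vecs, axis=1)
        nz = norms > 0
        vecs[nz] /= norms[nz, None]
        return GradientTable(self.bvals.copy(), vecs)


@dataclass
class DWIDataset:
    """A 4D diffusion acquisition: signal volumes + grid geometry + gradients."""

    signal: np.ndarray
    affine: np.ndarray
    gradients: GradientTable

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.signal.ndim != 4:
            raise ValidationError(f"signal must be 4D, got {self.signal.ndim}D")
        if self.affine.shape != (4, 4):
            raise ValidationError("affine must be 4x4")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValidationError("affine is singular")
        if self.signal.shape[3] != self.gradients.n_volumes:
            raise ConsistencyError(
                f"4D volume has {self.signal.shape[3]} volumes but the "
                f"gradient table describes {self.gradients.n_volumes}"
            )
        if not np.all(np.isfinite(self.signal)):
            raise ValidationError("signal contains non-finite values")

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.signal.shape[:3]


@dataclass
class LabelMap:
    """3D integer segmentation with a label-id -> nucleus-name dictionary.

    0 is reserved for background; every nonzero label present in the volume
    gets an entry in ``names`` (auto-filled as ``label_<k>`` when absent).
    """

    labels: np.ndarray
    affine: np.ndarray
    names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValidationError("labels array must have an integer dtype")
        if self.labels.ndim != 3:
            raise ValidationError("labels must be a 3D volume")
        if np.any(self.labels < 0):
            raise ValidationError("negative label ids are not allowed")
        self.affine = np.asarray(self.affine, dtype=float)
        self.names = {int(k): str(v) for k, v in self.names.items()}
        for k in self.present_labels():
            self.names.setdefault(int(k), f"label_{int(k)}")

    def present_labels(self) -> np.ndarray:
        """Sorted nonzero label ids present in the volume."""
        vals = np.unique(self.labels)
        return vals[vals > 0]

    def mask(self, label: int) -> np.ndarray:
        return self.labels == label


# --------------------------------------------------------------------------
# parsing helpers


def _parse_bvals(path: Path) -> np.ndarray:
    vals = np.loadtxt(path, ndmin=1)
    return np.atleast_1d(vals.ravel().astype(float))


def _parse_bvecs(path: Path) -> np.ndarray:
    arr = np.loadtxt(path, ndmin=2)
    if arr.shape[0] == 3:
        return arr.T  # FSL canonical: 3 rows x N columns
    if arr.shape[1] == 3:
        warnings.warn(
            f"{path}: bvecs appear transposed (N x 3 instead of FSL 3 x N); "
            "accepting the transposed layout",
            stacklevel=3,
        )
        return arr
    raise ValidationError(
        f"{path}: cannot interpret bvecs of shape {arr.shape}; expected "
        "3 x N (FSL) or N x 3"
    )


def read_dwi(
    volume_path,
    bval_path,
    bvec_path,
    *,
    renormalize_bvecs: bool = False,
    zero_fill_nonfinite: bool = False,
) -> DWIDataset:
    """Read a 4D NIfTI with FSL-style sidecars into a validated ``DWIDataset``.

    Parameters
    ----------
    renormalize_bvecs:
        rescale weighted directions whose norm deviates from 1 (otherwise a
        :class:`~dimani.errors.ValidationError` is raised).
    zero_fill_nonfinite:
        replace NaN/Inf voxels with 0 and warn instead of raising.
    """
    img = nib.load(str(volume_path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValidationError(f"{volume_path}: expected a 4D volume, got {data.ndim}D")
    if not np.all(np.isfinite(data)):
        if zero_fill_nonfinite:
            n = int(np.sum(~np.isfinite(data)))
            warnings.warn(f"{volume_path}: zero-filling {n} non-finite voxels")
            data = np.nan_to_num(data, nan=0.0, posinf=0.0, neginf=0.0)
        else:
            raise ValidationError(
                f"{volume_path}: non-finite voxels present; pass "
                "zero_fill_nonfinite=True to replace them with 0"
            )

    bvals = _parse_bvals(Path(bval_path))
    bvecs = _parse_bvecs(Path(bvec_path))
    if len(bvals) != len(bvecs):
        raise ConsistencyError(
            f"{len(bvals)} b-values but {len(bvecs)} gradient directions"
        )
    if len(bvals) != data.shape[3]:
        raise ConsistencyError(
            f"gradient table describes {len(bvals)} volumes but "
            f"{volume_path} holds {data.shape[3]}"
        )
    if renormalize_bvecs:
        norms = np.linalg.norm(bvecs, axis=1)
        nz = norms > 0
        bvecs = bvecs.copy()
        bvecs[nz] /= norms[nz, None]
    table = GradientTable(bvals, bvecs)
    return DWIDataset(signal=data, affine=img.affine, gradients=table)


def write_image(values: np.ndarray, affine: np.ndarray, path) -> None:
    """Write a 3D (or 4D) scalar array as a 32-bit float NIfTI-1 file."""
    values = np.asarray(values)
    if not np.all(np.isfinite(values)):
        raise ValidationError("refusing to write non-finite voxel values")
    img = nib.Nifti1Image(values.astype(np.float32), np.asarray(affine, dtype=float))
    nib.save(img, str(path))


def write_labelmap(labelmap: LabelMap, path) -> None:
    """Write a LabelMap volume as integer NIfTI-1 (names are NOT embedded;
    serialize them separately, e.g. with json)."""
    dtype = np.int16 if labelmap.labels.max(initial=0) < 2**15 else np.int32
    img = nib.Nifti1Image(labelmap.labels.astype(dtype), labelmap.affine)
    nib.save(img, str(path))


def load_names(path) -> dict[int, str]:
    """Load a ``{"1": "VLPv", ...}`` JSON mapping into ``{1: "VLPv", ...}``."""
    with open(path) as fh:
        raw = json.load(fh)
    return {int(k): str(v) for k, v in raw.items()}


def read_labelmap(path, names: dict[int, str] | None = None) -> LabelMap:
    """Read an integer-valued NIfTI segmentation.

    Floating-point storage is accepted as long as every voxel is within 1e-6
    of an integer (common after lossless format conversions).
    """
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 3:
        raise ValidationError(f"{path}: expected a 3D label volume, got {data.ndim}D")
    rounded = np.round(data)
    if np.any(np.abs(data - rounded) > 1e-6):
        bad = float(np.max(np.abs(data - rounded)))
        raise ValidationError(
            f"{path}: non-integer voxel values (max deviation {bad:g}); "
            "label maps must hold integer labels"
        )
    return LabelMap(
        labels=rounded.astype(np.int32), affine=img.affine, names=names or {}
    )
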