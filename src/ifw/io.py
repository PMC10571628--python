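"""Diffusion MRI input/output and geometry validation.

Reads 4-D diffusion-weighted NIfTI volumes together with FSL-dialect
b-value/b-vector text files (one whitespace-separated row of b-values;
three rows of direction components), scalar maps (free-water, CSF
fractional volume, iFW) and integer label maps, and enforces the geometry
contracts the rest of the toolkit relies on: all maps live on the same
grid as the diffusion data, already registered upstream.  No resampling
is ever performed here.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import nibabel as nib
import numpy as np

logger = logging.getLogger(__name__)

#: tolerance on |g| - 1 for b > 0 gradient directions (file-precision noise)
UNIT_NORM_TOL = 1e-3
#: tolerance (mm) on affine agreement between the DWI grid and any map
AFFINE_TOL = 1e-3
#: map kinds whose values must be fractions in [0, 1]
FRACTION_KINDS = frozenset({"fraction", "fw", "csfv", "ifw"})


@dataclass(frozen=True)
class AcquisitionScheme:
    """Per-volume diffusion weighting, gradient direction and echo time.

    Parameters
    ----------
    bvals : (n,) array
        b-value of each volume in s/mm^2.
    bvecs : (n, 3) array
        Unit gradient direction for each b > 0 volume; (0, 0, 0) for b = 0.
    echo_time : float
        Echo time of the acquisition in ms (needed for T2 compensation).
    """

    bvals: np.ndarray
    bvecs: np.ndarray
    echo_time: float

    def __post_init__(self) -> None:
        bvals = np.asarray(self.bvals, dtype=float).ravel()
        bvecs = np.asarray(self.bvecs, dtype=float)
        if bvecs.ndim != 2 or bvecs.shape[1] != 3:
            raise ValueError(f"bvecs must be (n, 3), got {bvecs.shape}")
        if bvals.shape[0] != bvecs.shape[0]:
            raise ValueError(
                f"bvals ({bvals.shape[0]}) and bvecs ({bvecs.shape[0]}) "
                "describe different numbers of volumes"
            )
        if np.any(bvals < 0):
            raise ValueError("negative b-values are not physical")
        if not np.any(bvals == 0):
            raise ValueError("scheme must contain at least one b=0 volume")
        norms = np.linalg.norm(bvecs, axis=1)
        bad = (bvals > 0) & (np.abs(norms - 1.0) > UNIT_NORM_TOL)
        if np.any(bad):
            raise ValueError(
                f"{int(bad.sum())} b>0 direction(s) deviate from unit norm by "
                f"more than {UNIT_NORM_TOL}; renormalize first (see read_dwi)"
            )
        bvals.setflags(write=False)
        bvecs.setflags(write=False)
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)
        object.__setattr__(self, "echo_time", float(self.echo_time))

    def __len__(self) -> int:
        return self.bvals.shape[0]

    @property
    def n_volumes(self) -> int:
        return len(self)

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals == 0

    @property
    def shells(self) -> np.ndarray:
        """Sorted unique b-values."""
        return np.unique(self.bvals)

    def subset(self, index: np.ndarray) -> "AcquisitionScheme":
        """Scheme restricted to the given volume indices / boolean mask."""
        index = np.asarray(index)
        return AcquisitionScheme(self.bvals[index], self.bvecs[index], self.echo_time)


def normalize_bvecs(bvals: np.ndarray, bvecs: np.ndarray) -> np.ndarray:
    """Renormalize b>0 directions to unit length, warning when they deviate.

    A zero direction paired with b > 0 is unrecoverable and raises.
    """
    bvals = np.asarray(bvals, dtype=float).ravel()
    bvecs = np.array(bvecs, dtype=float)
    norms = np.linalg.norm(bvecs, axis=1)
    weighted = bvals > 0
    if np.any(weighted & (norms == 0)):
        raise ValueError("zero gradient direction supplied for a b>0 volume")
    off = weighted & (np.abs(norms - 1.0) > UNIT_NORM_TOL)
    if np.any(off):
        warnings.warn(
            f"renormalized {int(off.sum())} non-unit b>0 gradient direction(s)",
            stacklevel=2,
        )
    scale = np.where(weighted & (norms > 0), norms, 1.0)
    return bvecs / scale[:, None]


@dataclass
class DwiDataset:
    """A 4-D diffusion-weighted volume with its scheme, mask and affine."""

    signal: np.ndarray
    scheme: AcquisitionScheme
    affine: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.signal.ndim != 4:
            raise ValueError(f"signal must be 4-D, got {self.signal.ndim}-D")
        if self.signal.shape[-1] != len(self.scheme):
            raise ValueError(
                f"signal has {self.signal.shape[-1]} volumes but the scheme "
                f"describes {len(self.scheme)}"
            )
        if self.mask.shape != self.signal.shape[:3]:
            raise ValueError(
                f"mask shape {self.mask.shape} does not match spatial "
                f"shape {self.signal.shape[:3]}"
            )
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.signal.shape[:3]

    @property
    def voxel_size(self) -> np.ndarray:
        """Voxel edge lengths (mm) from the affine."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))


@dataclass
class ScalarMap:
    """A named 3-D scalar volume on a known grid; NaN codes missing voxels."""

    values: np.ndarray
    affine: np.ndarray
    name: str = "map"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.values.ndim != 3:
            raise ValueError(f"scalar map must be 3-D, got {self.values.ndim}-D")


def check_geometry(
    shape_a: tuple, affine_a: np.ndarray, shape_b: tuple, affine_b: np.ndarray
) -> None:
    """Raise unless two grids agree in shape and affine (to AFFINE_TOL)."""
    if tuple(shape_a) != tuple(shape_b):
        raise ValueError(f"grid shape mismatch: {tuple(shape_a)} vs {tuple(shape_b)}")
    if not np.allclose(affine_a, affine_b, atol=AFFINE_TOL):
        raise ValueError(
            "affine mismatch beyond tolerance; maps must be registered to the "
            "diffusion grid upstream (no resampling is performed here)"
        )


def default_mask(
    signal: np.ndarray, scheme: AcquisitionScheme, threshold_fraction: float = 0.05
) -> np.ndarray:
    """Foreground mask from the mean b=0 signal.

    A voxel is kept when its mean b=0 signal exceeds ``threshold_fraction``
    of the 99th percentile of the mean b=0 image.
    """
    mean_b0 = np.asarray(signal, dtype=float)[..., scheme.b0_mask].mean(axis=-1)
    ref = np.percentile(mean_b0, 99)
    return mean_b0 > threshold_fraction * ref


def _read_bvals(path: Path) -> np.ndarray:
    rows = [ln.split() for ln in path.read_text().splitlines() if ln.strip()]
    if len(rows) != 1:
        raise ValueError(
            f"{path}: expected one row of b-values (FSL dialect), got {len(rows)} rows"
        )
    return np.array(rows[0], dtype=float)


def _read_bvecs(path: Path) -> np.ndarray:
    rows = [ln.split() for ln in path.read_text().splitlines() if ln.strip()]
    if len(rows) != 3:
        raise ValueError(
            f"{path}: expected three rows of direction components (FSL dialect), "
            f"got {len(rows)} rows"
        )
    arr = np.array(rows, dtype=float)
    return arr.T  # (n, 3)


def read_dwi(
    dwi_path: str | Path,
    bval_path: str | Path,
    bvec_path: str | Path,
    echo_time: float | None = None,
    mask_path: str | Path | None = None,
    mask_threshold: float = 0.05,
) -> DwiDataset:
    """Load a diffusion dataset from NIfTI + FSL bval/bvec files.

    ``echo_time`` (ms) may be omitted when a JSON sidecar next to the DWI
    provides it under ``echo_time_ms`` or ``EchoTime`` (seconds, BIDS-style).
    """
    dwi_path = Path(dwi_path)
    img = nib.load(str(dwi_path))
    signal = np.asarray(img.get_fdata(), dtype=float)
    if signal.ndim != 4:
        raise ValueError(f"{dwi_path}: expected a 4-D volume, got {signal.ndim}-D")

    bvals = _read_bvals(Path(bval_path))
    bvecs = _read_bvecs(Path(bvec_path))
    counts = (signal.shape[-1], bvals.shape[0], bvecs.shape[0])
    if len(set(counts)) != 1:
        raise ValueError(
            f"volume count mismatch: DWI has {counts[0]} volumes, bval file "
            f"{counts[1]}, bvec file {counts[2]}"
        )
    if np.any(bvals < 0):
        raise ValueError("negative b-values in bval file")

    if echo_time is None:
        echo_time = _sidecar_echo_time(dwi_path)
    bvecs = normalize_bvecs(bvals, bvecs)
    scheme = AcquisitionScheme(bvals, bvecs, echo_time)

    if mask_path is not None:
        mask_img = nib.load(str(mask_path))
        check_geometry(
            mask_img.shape[:3], mask_img.affine, signal.shape[:3], img.affine
        )
        mask = np.asarray(mask_img.get_fdata()) > 0.5
    else:
        mask = default_mask(signal, scheme, mask_threshold)
        logger.info("derived b0 foreground mask: %d voxels", int(mask.sum()))

    return DwiDataset(signal=signal, scheme=scheme, affine=img.affine, mask=mask)


def _sidecar_echo_time(dwi_path: Path) -> float:
    name = dwi_path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            name = name[: -len(suffix)]
            break
    sidecar = dwi_path.with_name(name + ".json")
    if not sidecar.exists():
        raise ValueError(
            f"echo_time not given and no JSON sidecar found at {sidecar}"
        )
    meta = json.loads(sidecar.read_text())
    if "echo_time_ms" in meta:
        return float(meta["echo_time_ms"])
    if "EchoTime" in meta:  # BIDS stores seconds
        return float(meta["EchoTime"]) * 1000.0
    raise ValueError(f"{sidecar}: no echo_time_ms or EchoTime key")


def select_shells(data: DwiDataset, max_b: float) -> DwiDataset:
    """Drop volumes with b > max_b (e.g. to exclude high-b non-Gaussian shells)."""
    if max_b <= 0:
        raise ValueError("max_b must be positive")
    keep = data.scheme.bvals <= max_b
    kept_b = data.scheme.bvals[keep]
    if not np.any(kept_b == 0) or not np.any(kept_b > 0):
        raise ValueError(
            "shell selection must retain at least one b=0 and one b>0 volume"
        )
    return DwiDataset(
        signal=data.signal[..., keep],
        scheme=data.scheme.subset(keep),
        affine=data.affine,
        mask=data.mask,
    )


def read_scalar_map(
    path: str | Path,
    reference: DwiDataset | None = None,
    kind: str = "fraction",
    name: str | None = None,
    clip_eps: float = 1e-2,
) -> ScalarMap:
    """Load a scalar map, checking geometry against ``reference`` when given.

    Fraction-kind maps (FW, CSFv, iFW) must lie in [0, 1]; values within
    ``clip_eps`` outside that range are treated as file-precision noise and
    clipped with a warning, larger excursions are an error.
    """
    img = nib.load(str(path))
    values = np.asarray(img.get_fdata(), dtype=float)
    if values.ndim == 4 and values.shape[-1] == 1:
        values = values[..., 0]
    if values.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D map, got {values.ndim}-D")
    if reference is not None:
        check_geometry(
            values.shape, img.affine, reference.spatial_shape, reference.affine
        )
    if kind in FRACTION_KINDS:
        finite = values[np.isfinite(values)]
        if finite.size and (finite.min() < -clip_eps or finite.max() > 1 + clip_eps):
            raise ValueError(
                f"{path}: fraction map has values in "
                f"[{finite.min():.4g}, {finite.max():.4g}], outside [0, 1] "
                f"beyond tolerance {clip_eps}"
            )
        out_of_range = np.isfinite(values) & ((values < 0) | (values > 1))
        if np.any(out_of_range):
            warnings.warn(
                f"{path}: clipped {int(out_of_range.sum())} voxel(s) to [0, 1] "
                "(file-precision noise)",
                stacklevel=2,
            )
            values = np.clip(values, 0.0, 1.0)
    return ScalarMap(values=values, affine=img.affine, name=name or kind)


def read_label_map(path: str | Path, reference: DwiDataset | None = None) -> ScalarMap:
    """Load an integer ROI label map (stored as ScalarMap with int-valued data)."""
    img = nib.load(str(path))
    values = np.asarray(img.get_fdata())
    if not np.allclose(values, np.round(values)):
        raise ValueError(f"{path}: label map contains non-integer values")
    if reference is not None:
        check_geometry(
            values.shape, img.affine, reference.spatial_shape, reference.affine
        )
    return ScalarMap(values=np.round(values), affine=img.affine, name="labels")


def write_scalar_map(map_: ScalarMap, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(map_.values.astype(np.float64), map_.affine), str(path))


def write_dwi(data: DwiDataset, prefix: str | Path) -> dict[str, Path]:
    """Write a dataset as <prefix>.nii.gz / .bval / .bvec / .json sidecar.

    Returns the paths written.  Round trip with :func:`read_dwi` preserves
    b-values exactly and directions to float text precision.
    """
    prefix = Path(prefix)
    paths = {
        "dwi": prefix.with_suffix(".nii.gz"),
        "bval": prefix.with_suffix(".bval"),
        "bvec": prefix.with_suffix(".bvec"),
        "json": prefix.with_suffix(".json"),
        "mask": Path(str(prefix) + "_mask.nii.gz"),
    }
    nib.save(nib.Nifti1Image(data.signal.astype(np.float64), data.affine), str(paths["dwi"]))
    nib.save(
        nib.Nifti1Image(data.mask.astype(np.uint8), data.affine), str(paths["mask"])
    )
    paths["bval"].write_text(
        " ".join(f"{b:.6g}" for b in data.scheme.bvals) + "\n"
    )
    rows = [
        " ".join(f"{v:.10f}" for v in data.scheme.bvecs[:, i]) for i in range(3)
    ]
    paths["bvec"].write_text("\n".join(rows) + "\n")
    paths["json"].write_text(
        json.dumps({"echo_time_ms": data.scheme.echo_time}, indent=2) + "\n"
    )
    return paths
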