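"""T2 compensation of the free-water fraction and the iFW map algebra.

The bi-tensor fit returns a *signal* fraction: at nonzero echo time the
free-water compartment (CSF-like T2, ~2 s at 3T) is far less attenuated
than tissue (cortical GM T2 ~90 ms at 3T), so the apparent fraction
overestimates the free-water volume fraction.  With mono-exponential
compartmental relaxation the apparent fraction is

    f_app = f * e_f / (f * e_f + (1 - f) * e_t),   e_x = exp(-TE / T2_x)

which inverts in closed form to

    f = f_app * k / (1 - f_app + f_app * k),       k = e_t / e_f.

Interstitial free water then removes the CSF partial volume voxelwise:

    iFW = max(FW_corrected - CSFv, 0)

(negative differences are projected to zero; the result is also clipped at
one to remain a fraction).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import ScalarMap, check_geometry

_FRACTION_TOL = 1e-6


@dataclass(frozen=True)
class RelaxationParams:
    """Echo time and per-compartment T2 values (all ms).

    Defaults: TE 109 ms (the toolkit's reference protocol), cortical GM
    T2 of 90 ms and CSF T2 of 2000 ms at 3T.
    """

    te: float = 109.0
    t2_tissue: float = 90.0
    t2_free: float = 2000.0

    def __post_init__(self) -> None:
        if self.te < 0:
            raise ValueError("echo time must be non-negative")
        if self.t2_tissue <= 0 or self.t2_free <= 0:
            raise ValueError("T2 values must be positive")
        if self.t2_free < self.t2_tissue:
            warnings.warn(
                "t2_free < t2_tissue: the correction direction reverses "
                "(free water would be *less* visible than tissue)",
                stacklevel=2,
            )

    @property
    def weight_tissue(self) -> float:
        return float(np.exp(-self.te / self.t2_tissue))

    @property
    def weight_free(self) -> float:
        return float(np.exp(-self.te / self.t2_free))


@dataclass
class IfwMap:
    """All stages of the iFW computation, retained for inspection."""

    fw_apparent: ScalarMap
    fw_corrected: ScalarMap
    csfv: ScalarMap
    ifw: ScalarMap


def _validate_fraction(values: np.ndarray, what: str) -> np.ndarray:
    finite = values[np.isfinite(values)]
    if finite.size and (
        finite.min() < -_FRACTION_TOL or finite.max() > 1 + _FRACTION_TOL
    ):
        raise ValueError(
            f"{what} outside [0, 1]: range "
            f"[{finite.min():.4g}, {finite.max():.4g}]"
        )
    return np.clip(values, 0.0, 1.0)


def apparent_fraction(f_true, params: RelaxationParams):
    """Forward T2 weighting: volume fraction -> apparent signal fraction."""
    f = _validate_fraction(np.asarray(f_true, dtype=float), "volume fraction")
    w_f, w_t = params.weight_free, params.weight_tissue
    return f * w_f / (f * w_f + (1.0 - f) * w_t)


def t2_correct(f_apparent, params: RelaxationParams):
    """Invert the compartmental T2 weighting of a signal fraction.

    Fixes 0 -> 0 and 1 -> 1 exactly; the result never exceeds the input
    when ``t2_free > t2_tissue`` (bias reduction).  Accepts scalars or
    arrays; NaN (missing) passes through.
    """
    arr = np.asarray(f_apparent, dtype=float)
    fa = _validate_fraction(arr, "apparent fraction")
    k = params.weight_tissue / params.weight_free
    out = fa * k / (1.0 - fa + fa * k)
    if np.isscalar(f_apparent) or arr.ndim == 0:
        return float(out)
    return out


def compute_ifw(fw_corrected: ScalarMap, csfv: ScalarMap) -> ScalarMap:
    """iFW = max(FW_corrected - CSFv, 0), clipped above at 1."""
    check_geometry(
        fw_corrected.values.shape,
        fw_corrected.affine,
        csfv.values.shape,
        csfv.affine,
    )
    _validate_fraction(fw_corrected.values, "fw_corrected")
    _validate_fraction(csfv.values, "csfv")
    ifw = np.clip(fw_corrected.values - csfv.values, 0.0, 1.0)
    return ScalarMap(values=ifw, affine=fw_corrected.affine, name="ifw")


def build_ifw_map(
    fw_apparent: ScalarMap, csfv: ScalarMap, params: RelaxationParams
) -> IfwMap:
    """Compose the T2 compensation and the CSF subtraction.

    Pure-CSF voxels (CSFv = 1) are eliminated entirely; deep tissue voxels
    (CSFv = 0) keep their corrected free-water value.
    """
    check_geometry(
        fw_apparent.values.shape, fw_apparent.affine, csfv.values.shape, csfv.affine
    )
    corrected = ScalarMap(
        values=np.asarray(t2_correct(fw_apparent.values, params)),
        affine=fw_apparent.affine,
        name="fw_corrected",
    )
    return IfwMap(
        fw_apparent=fw_apparent,
        fw_corrected=corrected,
        csfv=csfv,
        ifw=compute_ifw(corrected, csfv),
    )
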