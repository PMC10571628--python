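"""Two-compartment (bi-tensor) free-water model fitting.

The diffusion signal in each voxel is modelled as a mixture of an
anisotropic tissue compartment and an isotropic free-water compartment:

    S_i = S0 * [ (1 - f) * exp(-b_i g_i^T D g_i) + f * exp(-b_i d_free) ]

where ``f`` is the free-water *signal* fraction, ``D`` the tissue diffusion
tensor (mm^2/s) and ``d_free`` the diffusivity of free water at body
temperature (fixed, default 3.0e-3 mm^2/s).  Multi-shell data (several
nonzero b-values) conditions this voxelwise fit, so no spatial
regularization is applied.

Fitting is Gaussian least squares with box behaviour obtained through
unconstrained reparameterizations: a Cholesky factor for the tensor (PSD by
construction) and a clamped logistic for ``f`` (the logistic is scaled
slightly beyond [0, 1] so the boundary values are attainable at finite
parameter values; the reported fraction is clipped to [0, 1]).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.special import expit, logit

from .io import AcquisitionScheme, DwiDataset, ScalarMap

logger = logging.getLogger(__name__)

#: tensor entries are optimized in units of 1e-3 mm^2/s for conditioning
TENSOR_SCALE = 1.0e-3
#: logistic clamp: f = clip(_F_SPAN * expit(u) - _F_MARGIN, 0, 1)
_F_MARGIN = 0.05
_F_SPAN = 1.0 + 2.0 * _F_MARGIN

#: lower-triangular tensor component order (FSL convention)
TENSOR_COMPONENTS = ("Dxx", "Dxy", "Dyy", "Dxz", "Dyz", "Dzz")


@dataclass(frozen=True)
class FitConfig:
    """Tunable knobs of the voxelwise free-water fit.

    d_free : isotropic free-water diffusivity (mm^2/s), fixed during fitting.
    lambda_init : assumed tissue mean diffusivity (mm^2/s) used only to seed
        the free-water fraction from the highest-shell mean attenuation.
    """

    d_free: float = 3.0e-3
    max_iter: int = 200
    tol: float = 1e-12
    lambda_init: float = 0.7e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d_free <= 0:
            raise ValueError("d_free must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be positive")


@dataclass
class FreeWaterFit:
    """Result of the two-compartment fit in one voxel."""

    f_fw: float
    tensor: np.ndarray  # (3, 3) mm^2/s
    s0: float
    residual_rms: float
    converged: bool
    degenerate: bool = False  # tissue compartment indistinguishable from free water


@dataclass
class FreeWaterMaps:
    """Voxel maps produced by :func:`fit_volume` (NaN outside the mask)."""

    fw: ScalarMap
    tensor: np.ndarray  # (x, y, z, 6) lower-triangular, FSL order
    s0: ScalarMap
    residual: ScalarMap
    converged: np.ndarray
    degenerate: np.ndarray


# ---------------------------------------------------------------------------
# model algebra


def design_matrix(scheme: AcquisitionScheme) -> np.ndarray:
    """(n, 6) matrix B with b_i g_i^T D g_i = B @ d6 for lower-tri d6."""
    g = scheme.bvecs
    b = scheme.bvals
    return b[:, None] * np.column_stack(
        [
            g[:, 0] ** 2,
            2 * g[:, 0] * g[:, 1],
            g[:, 1] ** 2,
            2 * g[:, 0] * g[:, 2],
            2 * g[:, 1] * g[:, 2],
            g[:, 2] ** 2,
        ]
    )


def d6_from_tensor(tensor: np.ndarray) -> np.ndarray:
    t = np.asarray(tensor, dtype=float)
    return np.array([t[0, 0], t[0, 1], t[1, 1], t[0, 2], t[1, 2], t[2, 2]])


def tensor_from_d6(d6: np.ndarray) -> np.ndarray:
    dxx, dxy, dyy, dxz, dyz, dzz = d6
    return np.array([[dxx, dxy, dxz], [dxy, dyy, dyz], [dxz, dyz, dzz]])


def predict_signal(
    s0: float,
    f_fw: float,
    tensor: np.ndarray,
    scheme: AcquisitionScheme,
    d_free: float = 3.0e-3,
) -> np.ndarray:
    """Forward bi-tensor signal for every volume of the scheme."""
    b = scheme.bvals
    exponent = design_matrix(scheme) @ d6_from_tensor(tensor)
    tissue = np.exp(-exponent)
    water = np.exp(-b * d_free)
    return s0 * ((1.0 - f_fw) * tissue + f_fw * water)


def _f_from_u(u: float) -> float:
    return _F_SPAN * expit(u) - _F_MARGIN


def _u_from_f(f: float) -> float:
    return float(logit(np.clip((f + _F_MARGIN) / _F_SPAN, 1e-9, 1 - 1e-9)))


def _chol_to_d6(l6: np.ndarray) -> np.ndarray:
    """d6 (scaled units) of T = L L^T for L = [[a,0,0],[b,c,0],[d,e,g]]."""
    a, b, c, d, e, g = l6
    return np.array(
        [a * a, a * b, b * b + c * c, a * d, b * d + c * e, d * d + e * e + g * g]
    )


def _chol_jacobian(l6: np.ndarray) -> np.ndarray:
    """(6, 6) Jacobian d(d6)/d(l6)."""
    a, b, c, d, e, g = l6
    return np.array(
        [
            [2 * a, 0, 0, 0, 0, 0],
            [b, a, 0, 0, 0, 0],
            [0, 2 * b, 2 * c, 0, 0, 0],
            [d, 0, 0, a, 0, 0],
            [0, d, e, b, c, 0],
            [0, 0, 0, 2 * d, 2 * e, 2 * g],
        ]
    )


def _chol_from_tensor(tensor: np.ndarray, d_free: float) -> np.ndarray:
    """Lower-triangular factor (scaled units) of a PSD-floored tensor."""
    t = np.asarray(tensor, dtype=float) / TENSOR_SCALE
    t = 0.5 * (t + t.T)
    vals, vecs = np.linalg.eigh(t)
    vals = np.clip(vals, 1e-4, 0.999 * d_free / TENSOR_SCALE)
    t = (vecs * vals) @ vecs.T
    L = np.linalg.cholesky(t + 1e-12 * np.eye(3))
    return np.array([L[0, 0], L[1, 0], L[1, 1], L[2, 0], L[2, 1], L[2, 2]])


def tensor_eigenvalues(tensor: np.ndarray) -> np.ndarray:
    return np.linalg.eigvalsh(np.asarray(tensor, dtype=float))


def fractional_anisotropy(tensor: np.ndarray) -> float:
    ev = tensor_eigenvalues(tensor)
    md = ev.mean()
    denom = np.sqrt((ev**2).sum())
    if denom == 0:
        return 0.0
    return float(np.sqrt(1.5 * ((ev - md) ** 2).sum()) / denom)


# ---------------------------------------------------------------------------
# voxel fit


def _initial_guess(
    signal: np.ndarray, scheme: AcquisitionScheme, config: FitConfig, B: np.ndarray
) -> np.ndarray:
    b0 = scheme.b0_mask
    s0 = max(float(signal[b0].mean()), 1e-12)

    b_max = scheme.bvals.max()
    hi = scheme.bvals == b_max
    atten = np.clip(float(signal[hi].mean()) / s0, 1e-6, 1.0)
    e_t = np.exp(-b_max * config.lambda_init)
    e_f = np.exp(-b_max * config.d_free)
    f0 = float(np.clip((atten - e_t) / (e_f - e_t), 0.01, 0.95))

    # tensor seed: weighted linear LS on free-water-corrected log-attenuation
    water = np.exp(-scheme.bvals * config.d_free)
    tissue_atten = np.clip((signal / s0 - f0 * water) / (1.0 - f0), 1e-6, None)
    dwi = scheme.bvals > 0
    d6_0, *_ = np.linalg.lstsq(B[dwi], -np.log(tissue_atten[dwi]), rcond=None)
    l6_0 = _chol_from_tensor(tensor_from_d6(d6_0), config.d_free)
    return np.concatenate([[np.log(s0), _u_from_f(f0)], l6_0])


def _residuals_and_jac(theta, signal, bvals, B, d_free):
    ln_s0, u = theta[0], theta[1]
    l6 = theta[2:]
    s0 = np.exp(ln_s0)
    sig = expit(u)
    f = _F_SPAN * sig - _F_MARGIN
    d6 = TENSOR_SCALE * _chol_to_d6(l6)
    tissue = np.exp(-(B @ d6))
    water = np.exp(-bvals * d_free)
    model = s0 * ((1.0 - f) * tissue + f * water)

    jac = np.empty((signal.size, 8))
    jac[:, 0] = model
    jac[:, 1] = s0 * (water - tissue) * (_F_SPAN * sig * (1.0 - sig))
    dE = -(B @ (TENSOR_SCALE * _chol_jacobian(l6)))  # (n, 6) d(exponent)... sign folded
    jac[:, 2:] = (s0 * (1.0 - f) * tissue)[:, None] * dE
    return model - signal, jac


def fit_voxel(
    signal: np.ndarray, scheme: AcquisitionScheme, config: FitConfig | None = None
) -> FreeWaterFit:
    """Constrained least-squares bi-tensor fit for a single voxel.

    Degenerate voxels (tissue compartment isotropic with diffusivity at
    ``d_free`` — e.g. pure CSF, where any split between compartments fits
    equally well) are resolved toward ``f_fw = 1`` and flagged.
    """
    config = config or FitConfig()
    signal = np.asarray(signal, dtype=float).ravel()
    if signal.shape[0] != len(scheme):
        raise ValueError(
            f"signal has {signal.shape[0]} entries, scheme {len(scheme)}"
        )
    n_weighted = np.unique(
        np.round(
            np.column_stack([scheme.bvals, scheme.bvecs])[scheme.bvals > 0], 6
        ),
        axis=0,
    ).shape[0]
    if n_weighted < 8:
        raise ValueError(
            "need at least 8 distinct (b, direction) combinations with b>0"
        )

    if not np.all(np.isfinite(signal)) or np.max(signal, initial=0.0) <= 0:
        return FreeWaterFit(
            f_fw=np.nan,
            tensor=np.full((3, 3), np.nan),
            s0=np.nan,
            residual_rms=np.nan,
            converged=False,
        )

    # floor non-positive samples (magnitude data can hit zero at high b)
    s0_est = max(float(signal[scheme.b0_mask].mean()), np.max(signal))
    floor = 1e-6 * s0_est
    n_floored = int(np.sum(signal < floor))
    if n_floored:
        logger.debug("floored %d non-positive signal entries", n_floored)
        signal = np.maximum(signal, floor)

    B = design_matrix(scheme)
    theta0 = _initial_guess(signal, scheme, config, B)
    result = least_squares(
        lambda th: _residuals_and_jac(th, signal, scheme.bvals, B, config.d_free)[0],
        theta0,
        jac=lambda th: _residuals_and_jac(th, signal, scheme.bvals, B, config.d_free)[1],
        method="lm",
        xtol=config.tol,
        ftol=config.tol,
        gtol=config.tol,
        max_nfev=config.max_iter * 10,
    )

    s0 = float(np.exp(result.x[0]))
    f = float(np.clip(_f_from_u(result.x[1]), 0.0, 1.0))
    tensor = TENSOR_SCALE * tensor_from_d6(_chol_to_d6(result.x[2:]))

    # clip eigenvalues into the physical range [0, d_free]
    vals, vecs = np.linalg.eigh(tensor)
    if vals.min() < -1e-12 or vals.max() > config.d_free * (1 + 1e-9):
        vals = np.clip(vals, 0.0, config.d_free)
        tensor = (vecs * vals) @ vecs.T
        vals, vecs = np.linalg.eigh(tensor)

    degenerate = False
    md = float(vals.mean())
    if f < 1.0 and md > 0.95 * config.d_free and fractional_anisotropy(tensor) < 0.1:
        # ridge: tissue tensor mimics free water; resolve toward f = 1
        degenerate = True
        f = 1.0

    rms = float(np.sqrt(np.mean(result.fun**2)))
    return FreeWaterFit(
        f_fw=f,
        tensor=tensor,
        s0=s0,
        residual_rms=rms,
        converged=bool(result.status > 0),
        degenerate=degenerate,
    )


def fit_volume(data: DwiDataset, config: FitConfig | None = None) -> FreeWaterMaps:
    """Apply :func:`fit_voxel` over the dataset mask.

    Out-of-mask voxels are NaN in every output map.  Deterministic for
    fixed inputs (the fit has no stochastic component).
    """
    config = config or FitConfig()
    if not np.any(data.mask):
        raise ValueError("mask is empty")
    shape = data.spatial_shape
    fw = np.full(shape, np.nan)
    s0 = np.full(shape, np.nan)
    residual = np.full(shape, np.nan)
    tensor = np.full(shape + (6,), np.nan)
    converged = np.zeros(shape, dtype=bool)
    degenerate = np.zeros(shape, dtype=bool)

    for idx in zip(*np.nonzero(data.mask)):
        fit = fit_voxel(data.signal[idx], data.scheme, config)
        fw[idx] = fit.f_fw
        s0[idx] = fit.s0
        residual[idx] = fit.residual_rms
        if np.all(np.isfinite(fit.tensor)):
            tensor[idx] = d6_from_tensor(fit.tensor)
        converged[idx] = fit.converged
        degenerate[idx] = fit.degenerate

    n_failed = int(np.sum(data.mask & ~converged))
    if n_failed:
        logger.warning("%d in-mask voxel(s) failed to converge", n_failed)
    return FreeWaterMaps(
        fw=ScalarMap(fw, data.affine, "fw"),
        tensor=tensor,
        s0=ScalarMap(s0, data.affine, "s0"),
        residual=ScalarMap(residual, data.affine, "residual"),
        converged=converged,
        degenerate=degenerate,
    )


def grid_search_f(
    signal: np.ndarray,
    scheme: AcquisitionScheme,
    d_free: float = 3.0e-3,
    step: float = 1e-3,
) -> float:
    """Brute-force profile search over the free-water fraction.

    For each ``f`` on a regular grid the tissue tensor is obtained by a
    linearized (log-domain) fit of the free-water-corrected attenuation and
    the full nonlinear cost is evaluated; the grid minimizer is returned.
    Slow but independent of the nonlinear optimizer — used as an oracle.
    """
    signal = np.asarray(signal, dtype=float).ravel()
    b0 = scheme.b0_mask
    s0 = float(signal[b0].mean())
    B = design_matrix(scheme)
    dwi = scheme.bvals > 0
    water = np.exp(-scheme.bvals * d_free)
    pinv = np.linalg.pinv(B[dwi])

    fs = np.arange(0.0, 1.0 + step / 2, step)
    best_f, best_cost = 0.0, np.inf
    for f in fs:
        if f >= 1.0:
            model = s0 * water
        else:
            atten = np.clip((signal / s0 - f * water) / (1.0 - f), 1e-10, None)
            d6 = pinv @ (-np.log(atten[dwi]))
            model = s0 * ((1.0 - f) * np.exp(-(B @ d6)) + f * water)
        cost = float(np.sum((model - signal) ** 2))
        if cost < best_cost:
            best_cost, best_f = cost, float(f)
    return best_f
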