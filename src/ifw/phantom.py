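"""Synthetic multi-shell dMRI signals and longitudinal cohorts.

Two generators make the whole toolkit testable without scan data:

* a three-compartment voxel forward model (tissue tensor + interstitial
  free water + CSF, each with its own T2 weighting) sampled on a known
  acquisition scheme with optional Rician noise, so the fit -> T2
  compensation -> CSF subtraction pipeline can be checked against ground
  truth; and

* a three-group longitudinal ROI cohort (healthy controls and two
  clinical-high-risk subgroups) with per-subject random intercepts,
  group-specific baseline offsets and yearly slopes, and demographic
  covariates, so the mixed-effects statistics can be calibrated.

Ground truth is always returned (and serialized) alongside the data; tests
never re-derive it.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .fwfit import design_matrix, d6_from_tensor
from .io import AcquisitionScheme, DwiDataset, ScalarMap

GROUPS = ("HC", "CHR-NP", "CHR-P")

#: reference multi-shell protocol: volumes per shell at TE = 109 ms
REFERENCE_SHELLS = ((0, 5), (200, 3), (500, 6), (1000, 30))
REFERENCE_TE = 109.0


# ---------------------------------------------------------------------------
# gradient directions


def _sphere_energy(angles: np.ndarray) -> float:
    n = angles.size // 2
    theta, phi = angles[:n], angles[n:]
    st = np.sin(theta)
    x = np.column_stack([st * np.cos(phi), st * np.sin(phi), np.cos(theta)])
    d2_minus = ((x[:, None, :] - x[None, :, :]) ** 2).sum(-1)
    d2_plus = ((x[:, None, :] + x[None, :, :]) ** 2).sum(-1)
    iu = np.triu_indices(n, k=1)
    return float((1.0 / d2_minus[iu] + 1.0 / d2_plus[iu]).sum())


@lru_cache(maxsize=None)
def electrostatic_directions(n: int) -> np.ndarray:
    """n unit vectors spread by electrostatic repulsion (antipodally symmetric).

    Deterministic: initialized from a Fibonacci hemisphere and refined by
    L-BFGS on the pairwise Coulomb energy of the +/- point pairs.
    """
    if n < 1:
        raise ValueError("need at least one direction")
    i = np.arange(n) + 0.5
    # Fibonacci points on the upper hemisphere
    z = 1.0 - i / n
    phi = np.pi * (1 + 5**0.5) * i
    theta = np.arccos(np.clip(z, -1, 1))
    if n == 1:
        return np.array([[0.0, 0.0, 1.0]])
    res = minimize(
        _sphere_energy,
        np.concatenate([theta, phi]),
        method="L-BFGS-B",
        options={"maxiter": 500},
    )
    th, ph = res.x[:n], res.x[n:]
    st = np.sin(th)
    vecs = np.column_stack([st * np.cos(ph), st * np.sin(ph), np.cos(th)])
    vecs /= np.linalg.norm(vecs, axis=1, keepdims=True)
    vecs.setflags(write=False)
    return vecs


def default_scheme() -> AcquisitionScheme:
    """The toolkit's reference acquisition scheme.

    44 volumes: 5 at b=0, 3 at b=200, 6 at b=500 and 30 at b=1000 s/mm^2,
    echo time 109 ms; b>0 directions spread by electrostatic repulsion.
    """
    bvals, bvecs = [], []
    for b, count in REFERENCE_SHELLS:
        bvals.extend([float(b)] * count)
        if b == 0:
            bvecs.extend([[0.0, 0.0, 0.0]] * count)
        else:
            bvecs.extend(electrostatic_directions(count).tolist())
    return AcquisitionScheme(
        np.array(bvals), np.array(bvecs), echo_time=REFERENCE_TE
    )


# ---------------------------------------------------------------------------
# voxel forward model


@dataclass(frozen=True)
class VoxelTruth:
    """Ground-truth composition of a simulated voxel.

    The iFW target of the pipeline is ``f_interstitial`` by construction;
    the free-water compartment of the bi-tensor model lumps interstitial
    water and CSF together (both diffuse at d_free).
    """

    f_interstitial: float
    f_csf: float
    tensor: np.ndarray  # (3, 3) mm^2/s
    s0: float = 1000.0
    t2_tissue: float = 90.0
    t2_free: float = 2000.0

    def __post_init__(self) -> None:
        for name in ("f_interstitial", "f_csf"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.f_interstitial + self.f_csf > 1.0 + 1e-12:
            raise ValueError("f_interstitial + f_csf exceeds 1")
        object.__setattr__(
            self, "tensor", np.asarray(self.tensor, dtype=float).reshape(3, 3)
        )

    @property
    def f_free_total(self) -> float:
        return self.f_interstitial + self.f_csf


def random_tensor(
    rng: np.random.Generator,
    md_range: tuple[float, float] = (0.5e-3, 1.2e-3),
    ratio_range: tuple[float, float] = (1.0, 3.0),
) -> np.ndarray:
    """Random PSD tensor with mean diffusivity in ``md_range`` (mm^2/s).

    Eigenvalues (l, s, s) with l/s drawn from ``ratio_range`` and a random
    rotation; anisotropy is mild, mimicking cortical gray matter.
    """
    md = rng.uniform(*md_range)
    r = rng.uniform(*ratio_range)
    s = 3.0 * md / (r + 2.0)
    evals = np.array([r * s, s, s])
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    return (q * evals) @ q.T


def simulate_voxel(
    truth: VoxelTruth,
    scheme: AcquisitionScheme,
    snr: float = np.inf,
    seed: int = 0,
    d_free: float = 3.0e-3,
    noise: str = "rician",
) -> np.ndarray:
    """Forward three-compartment signal with per-compartment T2 weighting.

    S_i = s0 * [w_t (1 - F) exp(-b g^T D g) + w_f F exp(-b d_free)]
    with F = f_interstitial + f_csf and w_x = exp(-TE / T2_x).

    ``snr`` is defined on the mean noiseless b=0 signal; ``np.inf`` gives
    the exact forward model.  Noise is Rician by default (magnitude MRI),
    Gaussian on request for debugging; reproducible for a fixed seed.
    """
    if not snr > 0:
        raise ValueError("snr must be positive (np.inf for noiseless)")
    F = truth.f_free_total
    w_t = np.exp(-scheme.echo_time / truth.t2_tissue)
    w_f = np.exp(-scheme.echo_time / truth.t2_free)
    exponent = design_matrix(scheme) @ d6_from_tensor(truth.tensor)
    signal = truth.s0 * (
        w_t * (1.0 - F) * np.exp(-exponent)
        + w_f * F * np.exp(-scheme.bvals * d_free)
    )
    if np.isinf(snr):
        return signal
    sigma = float(signal[scheme.b0_mask].mean()) / snr
    rng = np.random.default_rng(seed)
    if noise == "rician":
        n1 = rng.normal(scale=sigma, size=signal.shape)
        n2 = rng.normal(scale=sigma, size=signal.shape)
        return np.sqrt((signal + n1) ** 2 + n2**2)
    if noise == "gaussian":
        return signal + rng.normal(scale=sigma, size=signal.shape)
    raise ValueError(f"unknown noise model {noise!r}")


def make_phantom_volume(
    f_interstitial: np.ndarray,
    f_csf: np.ndarray,
    scheme: AcquisitionScheme | None = None,
    snr: float = np.inf,
    seed: int = 0,
    md_range: tuple[float, float] = (0.5e-3, 1.2e-3),
    s0: float = 1000.0,
    t2_tissue: float = 90.0,
    t2_free: float = 2000.0,
    voxel_size_mm: float = 2.0,
) -> tuple[DwiDataset, dict[str, ScalarMap]]:
    """Phantom volume from 2-D (or 3-D) grids of ground-truth fractions.

    Each voxel gets an independent random tensor (seeded).  Returns the
    dataset plus truth maps: ``f_interstitial``, ``f_csf`` and their sum
    ``fw_total`` (the quantity the bi-tensor fit estimates after T2
    compensation).
    """
    f_int = np.atleast_3d(np.asarray(f_interstitial, dtype=float))
    f_c = np.atleast_3d(np.asarray(f_csf, dtype=float))
    if f_int.shape != f_c.shape:
        raise ValueError("fraction grids must share a shape")
    scheme = scheme or default_scheme()
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    rng = np.random.default_rng(seed)
    signal = np.empty(f_int.shape + (len(scheme),))
    it = np.ndindex(f_int.shape)
    for k, idx in enumerate(it):
        truth = VoxelTruth(
            f_interstitial=float(f_int[idx]),
            f_csf=float(f_c[idx]),
            tensor=random_tensor(rng, md_range=md_range),
            s0=s0,
            t2_tissue=t2_tissue,
            t2_free=t2_free,
        )
        signal[idx] = simulate_voxel(
            truth, scheme, snr=snr, seed=int(rng.integers(2**31))
        )
    data = DwiDataset(
        signal=signal,
        scheme=scheme,
        affine=affine,
        mask=np.ones(f_int.shape, dtype=bool),
    )
    truth_maps = {
        "f_interstitial": ScalarMap(f_int, affine, "f_interstitial"),
        "f_csf": ScalarMap(f_c, affine, "f_csf"),
        "fw_total": ScalarMap(f_int + f_c, affine, "fw_total"),
    }
    return data, truth_maps


# ---------------------------------------------------------------------------
# longitudinal cohort


@dataclass(frozen=True)
class CohortDesign:
    """Generative design of a three-group longitudinal ROI cohort.

    Group order everywhere is (HC, CHR-NP, CHR-P); sizes default to
    96/127/33 subjects.  The response is an iFW-like fraction: baseline
    mean ~0.12 with group offsets and yearly slopes of a few 1e-3, subject
    random-intercept sd 0.015 and residual sd 0.01.  Covariates: age
    uniform on 12-35 years, sex Bernoulli(1/2), intracranial volume
    lognormal around 1.5e6 mm^3.
    """

    n_per_group: tuple[int, int, int] = (96, 127, 33)
    baseline_mean: float = 0.12
    baseline_offsets: tuple[float, float, float] = (0.0, 0.008, 0.010)
    slopes: tuple[float, float, float] = (0.0005, 0.001, 0.004)
    age_effect: float = 0.0003  # per year of age
    sex_effect: float = 0.002
    icv_effect: float = -5e-9  # per mm^3
    residual_sd: float = 0.01
    intercept_sd: float = 0.015
    schedule: tuple[float, ...] = (0.0, 1.0, 2.0)
    age_range: tuple[float, float] = (12.0, 35.0)
    icv_log_mean: float = float(np.log(1.5e6))
    icv_log_sd: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.n_per_group):
            raise ValueError("group sizes must be positive")
        if self.residual_sd < 0 or self.intercept_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if self.schedule[0] != 0.0:
            raise ValueError("timepoint schedule must start at 0 (baseline)")


def simulate_cohort(
    design: CohortDesign,
    seed: int | None = None,
    rois: tuple[str, ...] = ("MPFC",),
    measure_name: str = "ifw",
) -> tuple[pd.DataFrame, dict]:
    """Simulate a tidy longitudinal ROI table plus its ground-truth record.

    value = baseline_mean + offset[group] + slope[group] * t
            + age_effect * age + sex_effect * sex + icv_effect * icv
            + u_subject + noise,   u ~ N(0, intercept_sd), noise ~ N(0, residual_sd)

    ROIs share the design but receive independent intercepts and noise.
    """
    rng = np.random.default_rng(design.seed if seed is None else seed)
    rows = []
    sid = 0
    for g_idx, (group, n) in enumerate(zip(GROUPS, design.n_per_group)):
        for _ in range(n):
            sid += 1
            subject = f"S{sid:04d}"
            age = rng.uniform(*design.age_range)
            sex = int(rng.random() < 0.5)
            icv = float(np.exp(rng.normal(design.icv_log_mean, design.icv_log_sd)))
            for roi in rois:
                u = rng.normal(0.0, design.intercept_sd) if design.intercept_sd else 0.0
                for t in design.schedule:
                    eps = (
                        rng.normal(0.0, design.residual_sd)
                        if design.residual_sd
                        else 0.0
                    )
                    value = (
                        design.baseline_mean
                        + design.baseline_offsets[g_idx]
                        + design.slopes[g_idx] * t
                        + design.age_effect * age
                        + design.sex_effect * sex
                        + design.icv_effect * icv
                        + u
                        + eps
                    )
                    rows.append(
                        {
                            "subject_id": subject,
                            "group": group,
                            "timepoint_years": float(t),
                            "roi": roi,
                            "measure_name": measure_name,
                            "value": value,
                            "age": age,
                            "sex": sex,
                            "icv": icv,
                        }
                    )
    table = pd.DataFrame(rows)
    truth = {
        k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(design).items()
    }
    truth["groups"] = list(GROUPS)
    truth["rois"] = list(rois)
    return table, truth


def write_cohort(
    table: pd.DataFrame, truth: dict, prefix: str | Path
) -> dict[str, Path]:
    """Serialize a cohort as TSV plus a ground-truth JSON."""
    prefix = Path(prefix)
    paths = {
        "table": prefix.with_suffix(".tsv"),
        "truth": Path(str(prefix) + "_truth.json"),
    }
    table.to_csv(paths["table"], sep="\t", index=False)
    paths["truth"].write_text(json.dumps(truth, indent=2, default=list) + "\n")
    return paths
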