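"""Two-dimensional parametric model of voxel spatial-frequency tuning.

Each V1 voxel is summarized by its pRF center (eccentricity ``rv`` in
degrees, retinotopic angle ``thetav`` in radians) and responds to a stimulus
through the local spatial frequency ``w_l`` (cycles/degree) and local
orientation ``theta_l`` at that center.  The response is log-Gaussian in
spatial frequency,

    beta_hat = A_v * exp(-log2(w_l * p_v)^2 / (2 sigma^2)),

with a preferred period that is affine in eccentricity and modulated by
orientation harmonics,

    p_v = (a*rv + b) * (1 + p1 cos 2(theta_l) + p2 cos 4(theta_l)
                          + p3 cos 2(theta_l - thetav) + p4 cos 4(theta_l - thetav)),
    A_v =              1 + A1 cos 2(theta_l) + A2 cos 4(theta_l)
                          + A3 cos 2(theta_l - thetav) + A4 cos 4(theta_l - thetav),

for 11 parameters total: sigma (octaves), a, b (degrees), and the
dimensionless modulations p1-p4, A1-A4.  p1/p2 and A1/A2 act in the absolute
reference frame (screen orientation: theta_l = 0 is vertical); p3/p4 and
A3/A4 act relative to the voxel's retinotopic angle (theta_l = thetav is
the orientation an annulus presents at that voxel).

Voxels are fit simultaneously with a normalized, precision-weighted
mean-squared-error loss: each voxel's observed and predicted 48-vectors are
L2-normalized (making the fit agnostic to absolute response amplitude) and
the squared error is divided by the voxel's response variance sigma_v^2, so
noisy voxels count less.  Minimization uses the AMSGrad variant of Adam with
analytic gradients.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .stimulus import FrequencyVector, GridSpec, build_frequency_vectors

logger = logging.getLogger("sfmap")

__all__ = [
    "PARAM_NAMES",
    "Model2DParams",
    "SubmodelMask",
    "VoxelDesign",
    "FitResult",
    "build_design",
    "filter_voxels",
    "preferred_period",
    "gain",
    "predict_response",
    "voxel_loss",
    "fit",
    "fit_many",
]

LN2 = math.log(2.0)

#: Canonical parameter order used by every array interface in this module.
PARAM_NAMES = ("sigma", "a", "b", "p1", "p2", "p3", "p4", "A1", "A2", "A3", "A4")


@dataclass(frozen=True)
class Model2DParams:
    """The 11 parameters of the full two-dimensional tuning model."""

    sigma: float = 2.0
    a: float = 0.1
    b: float = 0.3
    p1: float = 0.0
    p2: float = 0.0
    p3: float = 0.0
    p4: float = 0.0
    A1: float = 0.0
    A2: float = 0.0
    A3: float = 0.0
    A4: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma (bandwidth, octaves) must be positive")

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "Model2DParams":
        return cls(**{k: float(v) for k, v in zip(PARAM_NAMES, arr)})

    def replace(self, **kw) -> "Model2DParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class SubmodelMask:
    """Which parameter groups are free; masked parameters are fixed at 0.

    sigma is free in every submodel (no prediction is possible without a
    bandwidth).  The groups mirror how the parameters act: {a}, {b},
    {p1,p2} (absolute-orientation period), {p3,p4} (relative-orientation
    period), {A1,A2} (absolute-orientation gain), {A3,A4}
    (relative-orientation gain).
    """

    free_a: bool = True
    free_b: bool = True
    free_p_abs: bool = False
    free_p_rel: bool = False
    free_A_abs: bool = False
    free_A_rel: bool = False

    def free_flags(self) -> np.ndarray:
        """Boolean array over PARAM_NAMES."""
        return np.array(
            [
                True,  # sigma
                self.free_a,
                self.free_b,
                self.free_p_abs,
                self.free_p_abs,
                self.free_p_rel,
                self.free_p_rel,
                self.free_A_abs,
                self.free_A_abs,
                self.free_A_rel,
                self.free_A_rel,
            ]
        )

    @property
    def n_free(self) -> int:
        return int(self.free_flags().sum())

    def free_names(self) -> tuple[str, ...]:
        return tuple(n for n, f in zip(PARAM_NAMES, self.free_flags()) if f)

    def apply(self, params: Model2DParams) -> Model2DParams:
        """Zero out the masked parameters (a/b fixed at 0 when masked)."""
        arr = params.to_array()
        arr[~self.free_flags()] = 0.0
        return Model2DParams.from_array(arr)

    @classmethod
    def full(cls) -> "SubmodelMask":
        return cls(True, True, True, True, True, True)


# ---------------------------------------------------------------------------
# Design construction and voxel eligibility
# ---------------------------------------------------------------------------

@dataclass
class VoxelDesign:
    """Per-voxel stimulus coordinates for the two-dimensional model.

    For every voxel and every one of the 48 stimulus classes this stores the
    local spatial frequency (cycles/degree) and local orientation (radians,
    mod pi) evaluated at the pRF center.
    """

    ecc: np.ndarray        # (V,) degrees
    angle: np.ndarray      # (V,) radians in [0, 2pi)
    omega_l: np.ndarray    # (V, n_classes) cycles/degree
    theta_l: np.ndarray    # (V, n_classes) radians in [0, pi)
    harmonics: np.ndarray = field(repr=False, default=None)  # (V, n_classes, 4)

    def __post_init__(self) -> None:
        if self.harmonics is None:
            tl = self.theta_l
            rel = tl - self.angle[:, None]
            self.harmonics = np.stack(
                [np.cos(2 * tl), np.cos(4 * tl), np.cos(2 * rel), np.cos(4 * rel)],
                axis=-1,
            )

    @property
    def n_voxels(self) -> int:
        return self.ecc.shape[0]

    def subset(self, idx) -> "VoxelDesign":
        return VoxelDesign(
            self.ecc[idx], self.angle[idx], self.omega_l[idx], self.theta_l[idx],
            self.harmonics[idx],
        )


def build_design(
    ecc: np.ndarray,
    angle: np.ndarray,
    vectors: Sequence[FrequencyVector] | None = None,
) -> VoxelDesign:
    """Evaluate local frequency and orientation at each pRF center.

    theta_l is reduced mod pi before the relative angle theta_l - thetav is
    formed; the double-angle cosines make the two conventions commensurate.
    """
    vectors = list(vectors) if vectors is not None else build_frequency_vectors()
    ecc = np.asarray(ecc, dtype=float)
    angle = np.mod(np.asarray(angle, dtype=float), 2 * math.pi)
    if np.any(ecc <= 0):
        raise ValueError("voxel eccentricity must be positive")
    mags = np.array([v.magnitude for v in vectors])
    offs = np.array([math.atan2(v.angular_freq, v.radial_freq) for v in vectors])
    omega_l = mags[None, :] / (2 * math.pi * ecc[:, None])
    theta_l = np.mod(angle[:, None] + offs[None, :], math.pi)
    return VoxelDesign(ecc, angle, omega_l, theta_l)


def filter_voxels(
    ecc: np.ndarray,
    prf_size: np.ndarray,
    betas: np.ndarray,
    grid: GridSpec | None = None,
) -> np.ndarray:
    """Voxel eligibility mask for model fitting.

    Keeps voxels whose pRF center lies within the stimulus annulus by at
    least one pRF standard deviation on each side and whose mean response is
    non-negative (voxels with negative mean responses are typically
    artifact-dominated).
    """
    grid = grid or GridSpec()
    ecc = np.asarray(ecc, dtype=float)
    prf_size = np.asarray(prf_size, dtype=float)
    mean_beta = np.asarray(betas, dtype=float).mean(axis=-1)
    keep = (
        (ecc >= grid.inner_mask_radius + prf_size)
        & (ecc <= grid.max_eccentricity - prf_size)
        & (mean_beta >= 0)
    )
    if not keep.any():
        logger.warning("voxel filter kept no voxels")
    return keep


# ---------------------------------------------------------------------------
# Forward model
# ---------------------------------------------------------------------------

def preferred_period(params: Model2DParams, rv, thetav, thetal):
    """Preferred period p_v in degrees at (rv, thetav) for orientation thetal."""
    rv = np.asarray(rv, dtype=float)
    thetav = np.asarray(thetav, dtype=float)
    thetal = np.asarray(thetal, dtype=float)
    base = params.a * rv + params.b
    rel = thetal - thetav
    mod = (
        1.0
        + params.p1 * np.cos(2 * thetal)
        + params.p2 * np.cos(4 * thetal)
        + params.p3 * np.cos(2 * rel)
        + params.p4 * np.cos(4 * rel)
    )
    out = base * mod
    if np.any(out <= 0):
        raise ValueError("non-positive preferred period; parameters violate invariant")
    return float(out) if out.ndim == 0 else out


def gain(params: Model2DParams, thetav, thetal):
    """Dimensionless response gain A_v for a stimulus orientation thetal."""
    thetav = np.asarray(thetav, dtype=float)
    thetal = np.asarray(thetal, dtype=float)
    rel = thetal - thetav
    out = (
        1.0
        + params.A1 * np.cos(2 * thetal)
        + params.A2 * np.cos(4 * thetal)
        + params.A3 * np.cos(2 * rel)
        + params.A4 * np.cos(4 * rel)
    )
    if np.any(out <= 0):
        raise ValueError("non-positive gain; parameters violate invariant")
    return float(out) if out.ndim == 0 else out


def predict_response(params: Model2DParams, design: VoxelDesign) -> np.ndarray:
    """Predicted response amplitudes, shape (n_voxels, n_classes).

    The prediction peaks over frequency at w_l = 1/p_v with height A_v.
    """
    pv = preferred_period(params, design.ecc[:, None], design.angle[:, None], design.theta_l)
    av = gain(params, design.angle[:, None], design.theta_l)
    u = np.log2(design.omega_l * pv)
    return av * np.exp(-(u ** 2) / (2 * params.sigma ** 2))


def voxel_loss(betas: np.ndarray, predictions: np.ndarray, sigma_v2: float) -> float:
    """Normalized precision-weighted squared error for one voxel.

    Both vectors are L2-normalized before comparison, so the loss is zero
    whenever predictions are proportional to the observations and is
    insensitive to the absolute response amplitude; 1/sigma_v^2 weights the
    voxel by the precision of its response estimates.
    """
    betas = np.asarray(betas, dtype=float)
    predictions = np.asarray(predictions, dtype=float)
    nb, np_ = np.linalg.norm(betas), np.linalg.norm(predictions)
    if nb == 0 or np_ == 0:
        raise ValueError("zero-norm response vector")
    resid = betas / nb - predictions / np_
    return float(np.mean(resid ** 2) / sigma_v2)


# ---------------------------------------------------------------------------
# Fitting (AMSGrad with analytic gradients)
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    params: Model2DParams
    mask: SubmodelMask
    loss: float
    n_iter: int
    converged: bool


def _prepare_weights(sigma_v2: np.ndarray) -> np.ndarray:
    """Precision weights 1/sigma_v^2 with a floor for noiseless voxels."""
    w = np.asarray(sigma_v2, dtype=float).copy()
    pos = w > 0
    if pos.any():
        w[~pos] = w[pos].min()
    else:
        w[:] = 1.0
    return 1.0 / w


def _params_to_t(params: Model2DParams) -> np.ndarray:
    t = params.to_array()
    t[0] = math.log(t[0])
    return t


def _t_to_params(t: np.ndarray) -> Model2DParams:
    arr = t.copy()
    arr[0] = math.exp(arr[0])
    return Model2DParams.from_array(arr)


def _batched_loss_grad(t, lw2, harm, bn, wmask, ecc, pen_weight=10.0):
    """Objective and gradient for stacked subjects.

    t: (S, 11) unconstrained (t[:,0] = log sigma); lw2: (S,V,n) log2 of the
    local frequency; harm: (S,V,n,4) orientation harmonics; bn: (S,V,n)
    unit-normalized observed responses; wmask: (S,V) per-voxel weight
    (precision * eligibility, normalized to mean 1 over eligible voxels);
    ecc: (S,V).  Returns (J per subject, dJ/dt of shape (S,11)).
    """
    S, V, n = lw2.shape
    sigma = np.exp(t[:, 0])[:, None, None]
    a = t[:, 1][:, None]
    b = t[:, 2][:, None]
    p = t[:, 3:7]
    A = t[:, 7:11]

    base = a * ecc + b                                    # (S,V)
    pmod = 1.0 + np.einsum("svik,sk->svi", harm, p)       # (S,V,n)
    pv = base[:, :, None] * pmod
    pv_safe = np.maximum(pv, 1e-6)
    av = 1.0 + np.einsum("svik,sk->svi", harm, A)
    u = lw2 + np.log(pv_safe) / LN2
    E = np.exp(-(u ** 2) / (2 * sigma ** 2))
    pred = av * E

    nrm = np.sqrt(np.einsum("svi,svi->sv", pred, pred))
    nrm = np.maximum(nrm, 1e-12)
    h = pred / nrm[:, :, None]
    g = h - bn
    resid = np.einsum("svi,svi->sv", g, g) / n            # (S,V)
    J = np.einsum("sv,sv->s", wmask, resid)

    # soft positivity penalties on the period and the gain
    pen_p = np.maximum(1e-3 - pv, 0.0)
    pen_a = np.maximum(0.05 - av, 0.0)
    J = J + pen_weight * (
        np.mean(pen_p ** 2, axis=(1, 2)) + np.mean(pen_a ** 2, axis=(1, 2))
    )

    # dJ/dpred through the normalization
    hg = np.einsum("svi,svi->sv", h, g)
    G = (2.0 * wmask / (n * nrm))[:, :, None] * (g - h * hg[:, :, None])

    dav = G * E - (2.0 * pen_weight / (V * n)) * pen_a
    dA = np.einsum("svi,svik->sk", dav, harm)

    GP = G * pred
    dls = np.einsum("svi,svi->s", GP, u ** 2 / sigma ** 2)

    # chain to the preferred period (only where pv was not clamped)
    live = (pv > 1e-6).astype(float)
    Q = GP * (-u / (sigma ** 2 * LN2 * pv_safe)) * live
    Q = Q - (2.0 * pen_weight / (V * n)) * pen_p  # d relu(eps-pv)^2/dpv = -2 pen_p
    da = np.einsum("svi,svi->s", Q, ecc[:, :, None] * pmod)
    db = np.einsum("svi,svi->s", Q, pmod)
    dp = np.einsum("svi,svik->sk", Q * base[:, :, None], harm)

    grad = np.concatenate(
        [dls[:, None], da[:, None], db[:, None], dp, dA], axis=1
    )
    return J, grad


def _normalize_betas(betas: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    nrm = np.linalg.norm(betas, axis=-1)
    ok = nrm > 0
    safe = np.where(ok, nrm, 1.0)
    return betas / safe[..., None], ok


def fit_many(
    designs: Sequence[VoxelDesign],
    betas: Sequence[np.ndarray],
    sigma_v2: Sequence[np.ndarray] | None = None,
    mask: SubmodelMask | None = None,
    seed: int = 0,
    init: Model2DParams | Sequence[Model2DParams] | None = None,
    include_classes: np.ndarray | None = None,
    lr: float = 0.02,
    max_iter: int = 25_000,
    tol: float = 1e-6,
    tol_window: int = 100,
    min_voxels: int = 50,
) -> list[FitResult]:
    """Fit the model to several subjects simultaneously (vectorized).

    Subjects are padded to a common voxel count and stacked; each subject's
    objective and gradient are independent, so this is exactly equivalent to
    fitting them one by one, just faster.  ``include_classes`` restricts the
    fit (and the response normalization) to a subset of stimulus classes —
    used by the cross-validation folds.  Deterministic given data and
    initialization; ``seed`` is accepted for interface uniformity.
    """
    mask = mask or SubmodelMask.full()
    S = len(designs)
    if sigma_v2 is None:
        sigma_v2 = [np.ones(d.n_voxels) for d in designs]
    for d in designs:
        if d.n_voxels < min_voxels:
            raise ValueError(
                f"need at least {min_voxels} eligible voxels, got {d.n_voxels}"
            )

    n_all = designs[0].omega_l.shape[1]
    incl = (
        np.ones(n_all, bool) if include_classes is None
        else np.asarray(include_classes, bool)
    )
    n = int(incl.sum())
    Vmax = max(d.n_voxels for d in designs)

    lw2 = np.zeros((S, Vmax, n))
    harm = np.zeros((S, Vmax, n, 4))
    bn = np.zeros((S, Vmax, n))
    wmask = np.zeros((S, Vmax))
    ecc = np.ones((S, Vmax))
    for s, (d, be, sv2) in enumerate(zip(designs, betas, sigma_v2)):
        V = d.n_voxels
        lw2[s, :V] = np.log2(d.omega_l[:, incl])
        harm[s, :V] = d.harmonics[:, incl, :]
        bsub, ok = _normalize_betas(np.asarray(be, float)[:, incl])
        if not ok.all():
            logger.warning("skipping %d zero-norm voxels", int((~ok).sum()))
        bn[s, :V] = bsub
        w = _prepare_weights(sv2) * ok
        tot = w.sum()
        wmask[s, :V] = w / tot if tot > 0 else 0.0
        ecc[s, :V] = d.ecc

    if init is None:
        init_list = [Model2DParams()] * S
    elif isinstance(init, Model2DParams):
        init_list = [init] * S
    else:
        init_list = list(init)
    t = np.stack([_params_to_t(mask.apply(p)) for p in init_list])
    free = mask.free_flags()[None, :].astype(float)

    b1, b2, eps = 0.9, 0.999, 1e-8
    m = np.zeros_like(t)
    v = np.zeros_like(t)
    vhat = np.zeros_like(t)
    hist: list[np.ndarray] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        J, grad = _batched_loss_grad(t, lw2, harm, bn, wmask, ecc)
        grad = grad * free
        if not np.all(np.isfinite(grad)):
            raise FloatingPointError(f"non-finite gradient at iteration {it}")
        m = b1 * m + (1 - b1) * grad
        v = b2 * v + (1 - b2) * grad * grad
        np.maximum(vhat, v, out=vhat)
        t = t - lr * m / (np.sqrt(vhat) + eps)
        hist.append(J)
        if it > tol_window:
            prev = hist[it - 1 - tol_window]
            rel = np.abs(J - prev) / np.maximum(np.abs(prev), 1e-12)
            if np.all(rel < tol):
                converged = True
                break
    J, _ = _batched_loss_grad(t, lw2, harm, bn, wmask, ecc)
    return [
        FitResult(mask.apply(_t_to_params(t[s])), mask, float(J[s]), it, converged)
        for s in range(S)
    ]


def fit(
    design: VoxelDesign,
    betas: np.ndarray,
    sigma_v2: np.ndarray | None = None,
    mask: SubmodelMask | None = None,
    seed: int = 0,
    **kw,
) -> FitResult:
    """Fit the model to one subject's eligible voxels; see ``fit_many``."""
    sv = None if sigma_v2 is None else [sigma_v2]
    return fit_many([design], [betas], sv, mask=mask, seed=seed, **kw)[0]
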