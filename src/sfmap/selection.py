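"""Nested submodel comparison by stimulus-class cross-validation.

Fourteen submodels of the 11-parameter tuning model are compared.  The
bandwidth sigma is free in every submodel; the others free nested parameter
groups: eccentricity terms {a}, {b}, period-orientation terms {p1,p2}
(absolute) and {p3,p4} (relative), and gain-orientation terms {A1,A2}
(absolute) and {A3,A4} (relative).  Models 1-9 step through the plausible
period/gain combinations; models 10-14 add the relative-gain pair {A3,A4}
to models 3, 5, 6, 7 and 9.

Each submodel is fit per subject with 12-fold cross-validation over the 48
stimulus classes: 4 randomly-partitioned classes are held out per fold, the
model is fit to the remaining 44, and held-out predictions are assembled
across folds into one complete predicted response vector per voxel, which
is scored with the normalized precision-weighted loss.  The same partition
is used for every submodel and subject.  Per-subject losses are combined by
demeaning within subject (and restoring the grand mean for display); the
winner is the submodel with the lowest mean normalized loss, ties going to
the simpler (lower-id) submodel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model2d import (
    Model2DParams,
    SubmodelMask,
    VoxelDesign,
    _prepare_weights,
    fit_many,
    predict_response,
)

logger = logging.getLogger("sfmap")

__all__ = [
    "SubmodelSpec",
    "build_registry",
    "make_partition",
    "crossvalidate",
    "crossvalidate_cohort",
    "normalize_and_select",
]

N_CLASSES = 48
N_FOLDS = 12


@dataclass(frozen=True)
class SubmodelSpec:
    id: int
    mask: SubmodelMask
    label: str

    @property
    def n_free(self) -> int:
        return self.mask.n_free


def build_registry() -> list[SubmodelSpec]:
    """The 14 candidate submodels."""

    def m(a=False, b=False, p_abs=False, p_rel=False, A_abs=False, A_rel=False):
        return SubmodelMask(a, b, p_abs, p_rel, A_abs, A_rel)

    specs = [
        SubmodelSpec(1, m(b=True), "constant period"),
        SubmodelSpec(2, m(a=True), "scaling (line through origin)"),
        SubmodelSpec(3, m(a=True, b=True), "affine period"),
        SubmodelSpec(4, m(a=True, b=True, p_abs=True), "affine + absolute period"),
        SubmodelSpec(5, m(a=True, b=True, p_rel=True), "affine + relative period"),
        SubmodelSpec(6, m(a=True, b=True, p_abs=True, p_rel=True), "affine + full period"),
        SubmodelSpec(7, m(a=True, b=True, A_abs=True), "affine + absolute gain"),
        SubmodelSpec(8, m(a=True, b=True, p_abs=True, A_abs=True),
                     "absolute period + absolute gain"),
        SubmodelSpec(9, m(a=True, b=True, p_abs=True, p_rel=True, A_abs=True),
                     "full period + absolute gain"),
    ]
    # desaturated variants: add the relative-gain pair {A3, A4}
    for new_id, base_id in zip((10, 11, 12, 13, 14), (3, 5, 6, 7, 9)):
        base = specs[base_id - 1]
        mask = SubmodelMask(
            base.mask.free_a, base.mask.free_b, base.mask.free_p_abs,
            base.mask.free_p_rel, base.mask.free_A_abs, True,
        )
        specs.append(SubmodelSpec(new_id, mask, base.label + " + relative gain"))
    assert len(specs) == 14
    return specs


def make_partition(seed: int, n_classes: int = N_CLASSES, n_folds: int = N_FOLDS) -> list[np.ndarray]:
    """Random partition of the stimulus classes into 12 folds of 4."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_classes)
    return [np.sort(chunk) for chunk in np.array_split(perm, n_folds)]


def _cv_score(betas: np.ndarray, preds: np.ndarray, sigma_v2: np.ndarray) -> float:
    """Mean over voxels of the normalized precision-weighted loss."""
    w = _prepare_weights(sigma_v2)
    nb = np.linalg.norm(betas, axis=1)
    nh = np.linalg.norm(preds, axis=1)
    ok = (nb > 0) & (nh > 0)
    resid = betas[ok] / nb[ok, None] - preds[ok] / nh[ok, None]
    return float(np.mean(w[ok] * np.mean(resid ** 2, axis=1)))


def crossvalidate(
    design: VoxelDesign,
    betas: np.ndarray,
    sigma_v2: np.ndarray,
    submodel: SubmodelSpec,
    partition: list[np.ndarray],
    **fit_kw,
) -> float:
    """Cross-validated loss of one submodel for one subject."""
    return crossvalidate_cohort(
        [design], [betas], [sigma_v2], [submodel], partition, **fit_kw
    )["cv_loss"].iloc[0]


def crossvalidate_cohort(
    designs: list[VoxelDesign],
    betas: list[np.ndarray],
    sigma_v2: list[np.ndarray],
    submodels: list[SubmodelSpec] | None = None,
    partition: list[np.ndarray] | None = None,
    seed: int = 0,
    lr: float = 0.02,
    max_iter: int = 8000,
    fold_max_iter: int = 3000,
    tol: float = 1e-6,
    fold_tol: float = 1e-5,
    tol_window: int = 50,
    min_voxels: int = 50,
) -> pd.DataFrame:
    """CV losses for every subject x submodel (shared partition).

    For each submodel, a full-data fit provides a warm start for the 12
    fold fits (44 training classes each); held-out predictions are then
    assembled into a complete response vector per voxel and scored against
    the observed responses.  Returns a long table (subject, submodel_id,
    cv_loss); failed submodel fits get NaN.
    """
    submodels = submodels or build_registry()
    partition = partition if partition is not None else make_partition(seed)
    n_classes = designs[0].omega_l.shape[1]
    S = len(designs)
    rows = []
    for sm in submodels:
        try:
            warm = fit_many(
                designs, betas, sigma_v2, mask=sm.mask, lr=lr,
                max_iter=max_iter, tol=tol, tol_window=tol_window,
                min_voxels=min_voxels,
            )
            preds = [np.full_like(np.asarray(b, float), np.nan) for b in betas]
            for fold in partition:
                incl = np.ones(n_classes, bool)
                incl[fold] = False
                fits = fit_many(
                    designs, betas, sigma_v2, mask=sm.mask,
                    init=[w.params for w in warm], include_classes=incl,
                    lr=lr, max_iter=fold_max_iter, tol=fold_tol,
                    tol_window=tol_window, min_voxels=min_voxels,
                )
                for s in range(S):
                    full_pred = predict_response(fits[s].params, designs[s])
                    preds[s][:, fold] = full_pred[:, fold]
            for s in range(S):
                assert not np.isnan(preds[s]).any()
                rows.append(
                    {
                        "subject": s,
                        "submodel_id": sm.id,
                        "cv_loss": _cv_score(betas[s], preds[s], sigma_v2[s]),
                    }
                )
        except (FloatingPointError, ValueError) as err:
            logger.warning("submodel %d failed: %s", sm.id, err)
            for s in range(S):
                rows.append({"subject": s, "submodel_id": sm.id, "cv_loss": np.nan})
    return pd.DataFrame(rows)


def normalize_and_select(
    cv_table: pd.DataFrame,
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[SubmodelSpec, pd.DataFrame]:
    """Combine CV losses across subjects and pick the winning submodel.

    Within each subject the mean loss across submodels is subtracted (the
    quality of fit varies greatly between subjects) and the grand mean is
    restored for display.  The winner has the lowest mean normalized loss;
    ties go to the lower id.  68% confidence intervals come from
    bootstrapping subjects.
    """
    df = cv_table.dropna(subset=["cv_loss"]).copy()
    pivot = df.pivot_table(index="subject", columns="submodel_id", values="cv_loss")
    pivot = pivot.dropna(axis=0)  # subjects with complete results only
    if pivot.empty:
        raise ValueError("no subject has complete cross-validation results")
    grand = pivot.to_numpy().mean()
    norm = pivot.sub(pivot.mean(axis=1), axis=0) + grand

    mean_loss = norm.mean(axis=0)
    rng = np.random.default_rng(seed)
    S = norm.shape[0]
    boot = np.empty((n_boot, norm.shape[1]))
    vals = norm.to_numpy()
    for k in range(n_boot):
        boot[k] = vals[rng.integers(0, S, S)].mean(axis=0)
    lo, hi = np.percentile(boot, [16, 84], axis=0)

    summary = pd.DataFrame(
        {
            "submodel_id": norm.columns,
            "mean_norm_loss": mean_loss.to_numpy(),
            "ci16": lo,
            "ci84": hi,
        }
    ).reset_index(drop=True)
    # stable winner: lowest loss, ties to the simpler (lower-id) submodel
    order = summary.sort_values(["mean_norm_loss", "submodel_id"])
    win_id = int(order["submodel_id"].iloc[0])
    registry = {sm.id: sm for sm in build_registry()}
    winner = registry[win_id]
    logger.info("selected submodel %d (%s), %d free parameters",
                winner.id, winner.label, winner.n_free)
    return winner, summary
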