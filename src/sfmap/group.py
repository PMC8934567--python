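"""Group-level aggregation and report generation.

Per-subject parameter estimates are combined with a bootstrapped
precision-weighted mean: each of 100 bootstrap draws resamples subjects
with replacement and averages their median parameter estimates weighted by
the precision of their response amplitudes (mean 1/sigma_v^2 over fit
voxels), normalized by the summed weights so units are preserved.  From the
group parameter draws we generate the summary surfaces — preferred period
and relative gain as functions of eccentricity and retinotopic angle for
annulus/pinwheel/spiral and vertical/horizontal/diagonal stimuli — and the
meridian-split analysis, which fits the affine-period submodel separately
to voxels in the visual-field quadrants around the horizontal and vertical
meridians.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import model2d, selection, synth, tuning1d
from .model2d import Model2DParams, SubmodelMask
from .stimulus import GridSpec, build_frequency_vectors

logger = logging.getLogger("sfmap")

__all__ = [
    "GroupParams",
    "MeridianSplitResult",
    "subject_precision",
    "bootstrap_group_params",
    "period_surface",
    "gain_surface",
    "meridian_split",
    "run_pipeline",
]

#: theta_l conventions per stimulus category: relative categories present a
#: fixed orientation offset from the voxel's retinotopic angle; absolute
#: categories a fixed screen orientation (0 = vertical).
_RELATIVE_OFFSETS = {
    "annulus": 0.0,
    "pinwheel": math.pi / 2,
    "forward-spiral": -math.pi / 4,
    "reverse-spiral": math.pi / 4,
}
_ABSOLUTE_ORIENTATIONS = {
    "vertical": 0.0,
    "horizontal": math.pi / 2,
    "diagonals": math.pi / 4,
}


@dataclass
class GroupParams:
    """Bootstrap draws of the precision-weighted group-mean parameters."""

    draws: np.ndarray  # (n_boot, 11)

    @property
    def median(self) -> Model2DParams:
        return Model2DParams.from_array(np.median(self.draws, axis=0))

    def ci68(self) -> pd.DataFrame:
        lo, hi = np.percentile(self.draws, [16, 84], axis=0)
        return pd.DataFrame(
            {
                "parameter": model2d.PARAM_NAMES,
                "median": np.median(self.draws, axis=0),
                "ci16": lo,
                "ci84": hi,
            }
        )


def subject_precision(sigma_v2: np.ndarray) -> float:
    """Mean response precision (1/sigma_v^2) over a subject's fit voxels."""
    w = model2d._prepare_weights(np.asarray(sigma_v2, dtype=float))
    return float(np.mean(w))


def bootstrap_group_params(
    params: Sequence[Model2DParams] | np.ndarray,
    precisions: np.ndarray,
    n_boot: int = 100,
    seed: int = 0,
    n_draw: int | None = None,
) -> GroupParams:
    """Precision-weighted bootstrap of group-mean model parameters."""
    if not isinstance(params, np.ndarray):
        params = np.stack([p.to_array() for p in params])
    precisions = np.asarray(precisions, dtype=float)
    S = params.shape[0]
    if S == 1:
        return GroupParams(np.repeat(params, n_boot, axis=0))
    w = precisions.copy()
    bad = ~np.isfinite(w) | (w <= 0)
    if bad.any():
        logger.warning("non-positive precision for %d subject(s); weight capped", int(bad.sum()))
        w[bad] = w[~bad].max() if (~bad).any() else 1.0
    rng = np.random.default_rng(seed)
    n_draw = n_draw or S
    draws = np.empty((n_boot, params.shape[1]))
    for k in range(n_boot):
        idx = rng.integers(0, S, n_draw)
        draws[k] = np.sum(params[idx] * w[idx, None], axis=0) / np.sum(w[idx])
    return GroupParams(draws)


def _theta_l_for_category(category: str, angles: np.ndarray) -> np.ndarray:
    if category in _RELATIVE_OFFSETS:
        return np.mod(angles + _RELATIVE_OFFSETS[category], math.pi)
    if category in _ABSOLUTE_ORIENTATIONS:
        return np.full_like(angles, _ABSOLUTE_ORIENTATIONS[category])
    raise ValueError(f"unknown stimulus category {category!r}")


def period_surface(
    group: GroupParams,
    category: str,
    eccentricities: np.ndarray | None = None,
    angles: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Preferred-period predictions on an (eccentricity x angle) grid.

    Returns median and 16-84 percentile band over the bootstrap draws,
    each of shape (n_ecc, n_angle), plus the grid axes.
    """
    ecc = np.asarray(eccentricities if eccentricities is not None
                     else np.arange(1.0, 12.01, 0.25))
    ang = np.asarray(angles if angles is not None
                     else np.deg2rad(np.arange(0, 360, 1.0)))
    tl = _theta_l_for_category(category, ang)
    vals = np.empty((group.draws.shape[0], len(ecc), len(ang)))
    for k, draw in enumerate(group.draws):
        p = Model2DParams.from_array(draw)
        vals[k] = model2d.preferred_period(p, ecc[:, None], ang[None, :], tl[None, :])
    lo, hi = np.percentile(vals, [16, 84], axis=0)
    return {
        "eccentricity": ecc, "angle": ang,
        "median": np.median(vals, axis=0), "lo": lo, "hi": hi,
    }


def gain_surface(
    group: GroupParams,
    category: str,
    angles: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Relative gain vs retinotopic angle, normalized to mean 1 over angle."""
    ang = np.asarray(angles if angles is not None
                     else np.deg2rad(np.arange(0, 360, 1.0)))
    tl = _theta_l_for_category(category, ang)
    vals = np.empty((group.draws.shape[0], len(ang)))
    for k, draw in enumerate(group.draws):
        p = Model2DParams.from_array(draw)
        g = model2d.gain(p, ang, tl)
        vals[k] = g / np.mean(g)
    lo, hi = np.percentile(vals, [16, 84], axis=0)
    return {"angle": ang, "median": np.median(vals, axis=0), "lo": lo, "hi": hi}


# ---------------------------------------------------------------------------
# Meridian split
# ---------------------------------------------------------------------------

def horizontal_quadrant(theta_v: np.ndarray) -> np.ndarray:
    """True for angles in the quadrants around the horizontal meridians:
    theta_v in [0, pi/4] U (3pi/4, 5pi/4] U (7pi/4, 2pi]."""
    t = np.mod(np.asarray(theta_v, dtype=float), 2 * math.pi)
    return (
        (t <= math.pi / 4)
        | ((t > 3 * math.pi / 4) & (t <= 5 * math.pi / 4))
        | (t > 7 * math.pi / 4)
    )


@dataclass
class MeridianSplitResult:
    eccentricity: np.ndarray          # evaluation grid
    params_h: np.ndarray              # (S, 2): (a, b) per subject, horizontal set
    params_v: np.ndarray              # (S, 2): vertical set
    difference_median: np.ndarray     # horizontal - vertical period, per ecc
    difference_ci: np.ndarray         # (2, n_ecc): 16th / 84th percentiles


def meridian_split(
    subjects: Sequence[synth.SyntheticSubject],
    grid: GridSpec | None = None,
    eccentricities: np.ndarray | None = None,
    seed: int = 0,
    n_boot: int = 100,
    min_voxels: int = 50,
    **fit_kw,
) -> MeridianSplitResult:
    """Fit the affine-period submodel separately to horizontal- and
    vertical-meridian quadrants and bootstrap the period difference.

    Subjects with an empty quadrant (after eligibility filtering) are
    skipped with a warning.
    """
    grid = grid or GridSpec()
    ecc_grid = np.asarray(eccentricities if eccentricities is not None
                          else np.arange(1.0, 12.01, 0.5))
    mask3 = SubmodelMask(free_a=True, free_b=True)
    ph, pv = [], []
    for subj in subjects:
        keep = model2d.filter_voxels(subj.ecc, subj.prf_size, subj.betas, grid)
        horiz = horizontal_quadrant(subj.angle)
        pair = []
        for sel in (keep & horiz, keep & ~horiz):
            if sel.sum() < min_voxels:
                logger.warning("subject %s: quadrant has %d (<%d) voxels; skipped",
                               subj.subject_id, int(sel.sum()), min_voxels)
                pair = None
                break
            sub = subj.subset(sel)
            res = model2d.fit(sub.design(), sub.betas, sub.sigma_v2,
                              mask=mask3, min_voxels=min_voxels, **fit_kw)
            pair.append((res.params.a, res.params.b))
        if pair is not None:
            ph.append(pair[0])
            pv.append(pair[1])
    if not ph:
        raise ValueError("no subject had enough voxels in both quadrant sets")
    ph, pv = np.asarray(ph), np.asarray(pv)
    diff = (ph[:, 0, None] * ecc_grid + ph[:, 1, None]) - (
        pv[:, 0, None] * ecc_grid + pv[:, 1, None]
    )  # (S, n_ecc)
    rng = np.random.default_rng(seed)
    S = diff.shape[0]
    boot = np.stack([diff[rng.integers(0, S, S)].mean(axis=0) for _ in range(n_boot)])
    return MeridianSplitResult(
        ecc_grid, ph, pv,
        np.median(boot, axis=0), np.percentile(boot, [16, 84], axis=0),
    )


# ---------------------------------------------------------------------------
# Pipeline driver
# ---------------------------------------------------------------------------

_REQUIRED_FIELDS = ["seed", "outdir", "cohort"]
_REQUIRED_COHORT = ["n_subjects", "n_voxels"]


def _validate_config(config: dict) -> dict:
    for key in _REQUIRED_FIELDS:
        if key not in config:
            raise ValueError(f"config is missing required field {key!r}")
    for key in _REQUIRED_COHORT:
        if key not in config["cohort"]:
            raise ValueError(f"config is missing required field 'cohort.{key}'")
    cfg = {
        "noise_scale": 0.3,
        "jitter": 0.2,
        "n_boot_1d": 25,
        "n_boot_group": 100,
        "n_param_boots": 0,
        "run_selection": True,
        "skip_2d": False,
        "write_tables": False,
        "make_figures": True,
        "optimizer": {},
        "selection": {},
    }
    cfg.update(config)
    return cfg


def _simulate_stage(cfg: dict) -> list[synth.SyntheticSubject]:
    co = cfg["cohort"]
    return synth.simulate_cohort(
        co["n_subjects"],
        n_voxels=co["n_voxels"],
        noise_scale=cfg["noise_scale"],
        jitter=cfg["jitter"],
        seed=cfg["seed"],
    )


def run_pipeline(config: dict) -> dict:
    """Run simulate -> filter -> 1D fits -> 2D fits -> selection -> report.

    ``config`` must contain ``seed``, ``outdir`` and ``cohort`` (with
    ``n_subjects`` and ``n_voxels``); everything else has defaults.  All
    randomness derives from ``seed``, so two runs with the same config are
    identical.  Returns a manifest dict (also written as JSON).
    """
    cfg = _validate_config(config)
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    grid = GridSpec()
    vectors = build_frequency_vectors()
    manifest: dict = {"config": {k: v for k, v in cfg.items() if k != "outdir"},
                      "stages": []}

    # --- simulate -----------------------------------------------------
    subjects = _simulate_stage(cfg)
    if cfg["write_tables"]:
        for subj in subjects:
            synth.write_table(subj, outdir / "subjects")
    manifest["stages"].append({"stage": "simulate", "n_subjects": len(subjects)})

    # --- filter -------------------------------------------------------
    eligible = [model2d.filter_voxels(s.ecc, s.prf_size, s.betas, grid) for s in subjects]
    fit_subjects = [s.subset(e) for s, e in zip(subjects, eligible)]
    manifest["stages"].append(
        {"stage": "filter", "eligible": [int(e.sum()) for e in eligible]}
    )

    # --- 1D tuning curves --------------------------------------------
    rows_1d = []
    for s_idx, subj in enumerate(subjects):
        for cat in tuning1d.PRIMARY_CATEGORIES:
            boots = tuning1d.bootstrap_bins(
                subj, cat, n_boot=cfg["n_boot_1d"],
                seed=cfg["seed"] * 1000 + s_idx, vectors=vectors,
                eligible=eligible[s_idx],
            )
            if boots.empty:
                continue
            agg = boots.groupby("bin_center_deg")["preferred_period"].agg(
                median="median",
                spread=lambda x: np.percentile(x, 84) - np.percentile(x, 16),
            )
            for center, row in agg.iterrows():
                rows_1d.append(
                    {
                        "subject": subj.subject_id,
                        "category": cat,
                        "bin_center_deg": center,
                        "period_median": row["median"],
                        "period_spread": row["spread"],
                    }
                )
    df_1d = pd.DataFrame(rows_1d)
    df_1d.to_csv(outdir / "tuning1d_subjects.csv", index=False)

    rows_grp = []
    for cat in tuning1d.PRIMARY_CATEGORIES:
        sub = df_1d[df_1d["category"] == cat]
        for center, grp in sub.groupby("bin_center_deg"):
            est = tuning1d.group_mean(
                grp["period_median"].to_numpy(), grp["period_spread"].to_numpy(),
                n_boot=cfg["n_boot_group"], seed=cfg["seed"] + 17,
            )
            lo, hi = est.ci68
            rows_grp.append(
                {
                    "category": cat,
                    "bin_center_deg": center,
                    "period": est.median,
                    "ci16": lo,
                    "ci84": hi,
                }
            )
    df_grp = pd.DataFrame(rows_grp)
    df_grp.to_csv(outdir / "tuning1d_group.csv", index=False)
    affine = {
        cat: tuning1d.fit_affine(
            df_grp.loc[df_grp["category"] == cat, "bin_center_deg"],
            df_grp.loc[df_grp["category"] == cat, "period"],
        )
        for cat in tuning1d.PRIMARY_CATEGORIES
        if (df_grp["category"] == cat).sum() >= 3
    }
    manifest["stages"].append(
        {"stage": "fit-1d", "affine": {c: list(v) for c, v in affine.items()}}
    )

    if cfg["skip_2d"]:
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        return manifest

    # --- selection ----------------------------------------------------
    designs = [s.design(vectors) for s in fit_subjects]
    betas = [s.betas for s in fit_subjects]
    sv2 = [s.sigma_v2 for s in fit_subjects]
    sel_kw = dict(cfg["selection"])
    winner_mask = SubmodelMask(True, True, True, True, True, False)  # model 9
    if cfg["run_selection"]:
        partition = selection.make_partition(cfg["seed"] + 5)
        cv = selection.crossvalidate_cohort(
            designs, betas, sv2, partition=partition, **sel_kw
        )
        cv.to_csv(outdir / "selection_cv.csv", index=False)
        winner, summary = selection.normalize_and_select(cv, seed=cfg["seed"] + 7)
        summary.to_csv(outdir / "selection_summary.csv", index=False)
        (outdir / "selection.json").write_text(
            json.dumps({"winner_id": winner.id, "n_free": winner.n_free,
                        "label": winner.label}, indent=2)
        )
        winner_mask = winner.mask
        manifest["stages"].append(
            {"stage": "select", "winner_id": winner.id, "n_free": winner.n_free}
        )

    # --- 2D fits ------------------------------------------------------
    opt_kw = dict(cfg["optimizer"])
    fits = model2d.fit_many(designs, betas, sv2, mask=winner_mask, **opt_kw)
    rows_fit = []
    for subj, res in zip(fit_subjects, fits):
        rows_fit.append(
            {"subject": subj.subject_id, "boot_idx": -1,
             **dict(zip(model2d.PARAM_NAMES, res.params.to_array()))}
        )
    # per-subject parameter CIs from bootstrap response sets
    for b_idx in range(cfg["n_param_boots"]):
        boot_betas = [s.bootstraps[:, b_idx % s.bootstraps.shape[1], :] for s in fit_subjects]
        bfits = model2d.fit_many(
            designs, boot_betas, sv2, mask=winner_mask,
            init=[r.params for r in fits], **opt_kw,
        )
        for subj, res in zip(fit_subjects, bfits):
            rows_fit.append(
                {"subject": subj.subject_id, "boot_idx": b_idx,
                 **dict(zip(model2d.PARAM_NAMES, res.params.to_array()))}
            )
    df_fit = pd.DataFrame(rows_fit)
    df_fit.to_csv(outdir / "model2d_params.csv", index=False)
    manifest["stages"].append(
        {"stage": "fit-2d",
         "losses": [float(r.loss) for r in fits],
         "converged": [bool(r.converged) for r in fits]}
    )

    # --- group report -------------------------------------------------
    point = df_fit[df_fit["boot_idx"] == -1]
    med_params = point[list(model2d.PARAM_NAMES)].to_numpy()
    precisions = np.array([subject_precision(s) for s in sv2])
    gp = bootstrap_group_params(
        med_params, precisions, n_boot=cfg["n_boot_group"], seed=cfg["seed"] + 23
    )
    gp.ci68().to_csv(outdir / "group_params.csv", index=False)

    surf_rows = []
    for cat in list(_RELATIVE_OFFSETS) + list(_ABSOLUTE_ORIENTATIONS):
        surf = period_surface(gp, cat, angles=np.deg2rad(np.arange(0, 360, 15.0)))
        mid = np.searchsorted(surf["angle"], 0.0)
        for e_idx, e in enumerate(surf["eccentricity"]):
            surf_rows.append(
                {"category": cat, "eccentricity": float(e),
                 "period_at_horiz_meridian": float(surf["median"][e_idx, mid])}
            )
    pd.DataFrame(surf_rows).to_csv(outdir / "period_surfaces.csv", index=False)

    try:
        split = meridian_split(subjects, grid, seed=cfg["seed"] + 29, **opt_kw)
        pd.DataFrame(
            {
                "eccentricity": split.eccentricity,
                "difference_median": split.difference_median,
                "ci16": split.difference_ci[0],
                "ci84": split.difference_ci[1],
            }
        ).to_csv(outdir / "meridian_split.csv", index=False)
        manifest["stages"].append({"stage": "report", "meridian_split": "ok"})
    except ValueError as err:
        manifest["stages"].append({"stage": "report", "meridian_split": str(err)})

    if cfg["make_figures"]:
        _make_figures(outdir, df_grp, gp)

    import sfmap

    manifest["versions"] = {"sfmap": sfmap.__version__, "numpy": np.__version__}
    manifest["seed"] = cfg["seed"]
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def _make_figures(outdir: Path, df_grp: pd.DataFrame, gp: GroupParams) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for cat, grp in df_grp.groupby("category"):
        ax.errorbar(
            grp["bin_center_deg"], grp["period"],
            yerr=[grp["period"] - grp["ci16"], grp["ci84"] - grp["period"]],
            label=cat, marker="o", capsize=2,
        )
    ax.set_xlabel("eccentricity (deg)")
    ax.set_ylabel("preferred period (deg)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(outdir / "fig_period_vs_eccentricity.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 4))
    for cat in ("annulus", "pinwheel", "vertical", "horizontal"):
        surf = period_surface(gp, cat, eccentricities=np.array([5.0]))
        ax.plot(np.rad2deg(surf["angle"]), surf["median"][0], label=cat)
        ax.fill_between(np.rad2deg(surf["angle"]), surf["lo"][0], surf["hi"][0], alpha=0.2)
    ax.set_xlabel("retinotopic angle (deg)")
    ax.set_ylabel("preferred period at 5 deg (deg)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(outdir / "fig_period_vs_angle.png", dpi=120)
    plt.close(fig)
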