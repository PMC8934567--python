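"""Synthetic voxel-response tables with known ground truth.

Emulates the data product of a retinotopy experiment combined with
GLM-based response estimation: for each voxel, a pRF location and size, 48
response amplitudes (one per stimulus class, in percent-signal-change-like
units), per-stimulus uncertainty half-ranges, and 100 bootstrap replicates
across the 12 runs of the session.  Noiseless responses are exactly the
two-dimensional model's forward prediction at the pRF center, so every
downstream estimator can be validated by parameter recovery.

The noise model is deliberately simple: additive Gaussian noise at the run
level, homoscedastic within a voxel, with per-voxel noise scales drawn
lognormally (a 10x spread between the 16th and 84th percentile across
voxels) so that precision weighting is exercised nontrivially.  Response
amplitudes are run means; bootstraps are means of runs resampled with
replacement; the per-stimulus uncertainty is one-half of the 68-percentile
range of the bootstraps.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .model2d import Model2DParams, VoxelDesign, build_design, predict_response
from .stimulus import FrequencyVector, build_frequency_vectors

logger = logging.getLogger("sfmap")

__all__ = [
    "SyntheticSubject",
    "TEMPLATE_MODEL9",
    "sample_prf_locations",
    "simulate_subject",
    "simulate_cohort",
    "jitter_params",
    "write_table",
    "read_table",
]

#: Group-level operating point used as the default ground-truth template:
#: preferred period 0.12*r + 0.35 degrees, 2.2-octave bandwidth, an
#: annular/vertical period advantage of roughly equal absolute and relative
#: magnitude, and a ~8% vertical-over-horizontal gain advantage.
TEMPLATE_MODEL9 = Model2DParams(
    sigma=2.2, a=0.12, b=0.35,
    p1=0.07, p2=0.02, p3=0.07, p4=0.01,
    A1=0.04, A2=0.02, A3=0.0, A4=0.0,
)


@dataclass
class SyntheticSubject:
    """One simulated subject's voxel response table.

    betas are across-run means; bootstraps (n_boot, per voxel and class) are
    means over runs resampled with replacement; sigma_vi is half the
    68-percentile range of the bootstraps.  run_amplitudes keeps the
    run-level replicates so run-bootstrap analyses can be reproduced.
    """

    subject_id: str
    ecc: np.ndarray           # (V,) degrees
    angle: np.ndarray         # (V,) radians in [0, 2pi)
    prf_size: np.ndarray      # (V,) degrees
    betas: np.ndarray         # (V, 48)
    sigma_vi: np.ndarray      # (V, 48)
    bootstraps: np.ndarray    # (V, n_boot, 48)
    run_amplitudes: np.ndarray  # (V, n_runs, 48)
    ground_truth: Model2DParams | None = None
    noise_scale: float = 0.0
    seed: int | None = None

    @property
    def n_voxels(self) -> int:
        return self.ecc.shape[0]

    @property
    def n_runs(self) -> int:
        return self.run_amplitudes.shape[1]

    @property
    def sigma_v2(self) -> np.ndarray:
        """Per-voxel response variance: mean over classes of sigma_vi^2."""
        return np.mean(self.sigma_vi ** 2, axis=1)

    def design(self, vectors: Sequence[FrequencyVector] | None = None) -> VoxelDesign:
        return build_design(self.ecc, self.angle, vectors)

    def subset(self, idx) -> "SyntheticSubject":
        return SyntheticSubject(
            self.subject_id, self.ecc[idx], self.angle[idx], self.prf_size[idx],
            self.betas[idx], self.sigma_vi[idx], self.bootstraps[idx],
            self.run_amplitudes[idx], self.ground_truth, self.noise_scale, self.seed,
        )


def sample_prf_locations(
    n_voxels: int,
    seed: int,
    ecc_range: tuple[float, float] = (0.5, 13.0),
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sample pRF centers and sizes for a simulated V1 hemifield pair.

    Eccentricity is log-uniform on ``ecc_range`` (extending slightly beyond
    the stimulated 1-12 degrees so the border-exclusion rules have work to
    do), polar angle uniform on [0, 2pi), and pRF size follows the familiar
    near-linear growth with eccentricity, 0.1*r + 0.15 degrees, with 20%
    lognormal jitter.
    """
    if n_voxels < 1:
        raise ValueError("n_voxels must be >= 1")
    rng = np.random.default_rng(seed)
    lo, hi = ecc_range
    ecc = np.exp(rng.uniform(math.log(lo), math.log(hi), n_voxels))
    angle = rng.uniform(0.0, 2 * math.pi, n_voxels)
    prf_size = (0.1 * ecc + 0.15) * np.exp(rng.normal(0.0, 0.2, n_voxels))
    return ecc, angle, prf_size


def simulate_subject(
    subject_id: str,
    ground_truth: Model2DParams,
    n_voxels: int = 3000,
    noise_scale: float = 0.3,
    seed: int = 0,
    n_runs: int = 12,
    n_boot: int = 100,
    vectors: Sequence[FrequencyVector] | None = None,
    noise_spread: float = math.log(10) / 2,
) -> SyntheticSubject:
    """Simulate one subject's GLM-style voxel response table.

    ``noise_scale`` is the median run-level noise standard deviation in
    response units (the model's peak response is ~1 for unit gain);
    ``noise_spread`` is the lognormal sigma of the per-voxel noise scales
    (the default gives a 10x spread over +-1 sd).
    """
    rng = np.random.default_rng(seed)
    ecc, angle, prf_size = sample_prf_locations(n_voxels, int(rng.integers(2 ** 31)))
    if np.any(ecc <= 0):
        raise ValueError("voxel at the fovea (r=0): local frequency undefined")
    design = build_design(ecc, angle, vectors)
    clean = predict_response(ground_truth, design)  # (V, 48)

    sd_v = noise_scale * np.exp(rng.normal(0.0, noise_spread, n_voxels))
    runs = clean[:, None, :] + sd_v[:, None, None] * rng.standard_normal(
        (n_voxels, n_runs, clean.shape[1])
    )
    betas = runs.mean(axis=1)
    boot_idx = rng.integers(0, n_runs, size=(n_boot, n_runs))
    # (V, n_boot, 48): mean over resampled runs
    bootstraps = runs[:, boot_idx, :].mean(axis=2)
    q16, q84 = np.percentile(bootstraps, [16, 84], axis=1)
    sigma_vi = 0.5 * (q84 - q16)
    if noise_scale == 0:
        sigma_vi[:] = 0.0
        betas = clean.copy()
        bootstraps = np.repeat(clean[:, None, :], n_boot, axis=1)
        runs = np.repeat(clean[:, None, :], n_runs, axis=1)
    return SyntheticSubject(
        subject_id, ecc, angle, prf_size, betas, sigma_vi, bootstraps, runs,
        ground_truth=ground_truth, noise_scale=noise_scale, seed=seed,
    )


def jitter_params(template: Model2DParams, rng: np.random.Generator,
                  jitter: float = 0.2) -> Model2DParams:
    """Multiply each nonzero parameter by an independent uniform factor in
    [1-jitter, 1+jitter] — simple between-subject heterogeneity."""
    arr = template.to_array()
    factors = rng.uniform(1 - jitter, 1 + jitter, arr.shape)
    return Model2DParams.from_array(np.where(arr != 0, arr * factors, 0.0))


def simulate_cohort(
    n_subjects: int,
    template: Model2DParams = TEMPLATE_MODEL9,
    n_voxels: int = 3000,
    noise_scale: float = 0.3,
    seed: int = 0,
    jitter: float = 0.2,
    **kw,
) -> list[SyntheticSubject]:
    """Simulate a cohort; each subject's ground truth is the template with
    ±``jitter`` multiplicative heterogeneity (0 for identical subjects)."""
    subjects = []
    for k in range(n_subjects):
        rng = np.random.default_rng([seed, k])
        gt = jitter_params(template, rng, jitter) if jitter > 0 else template
        subjects.append(
            simulate_subject(
                f"sub-{k + 1:02d}", gt, n_voxels=n_voxels,
                noise_scale=noise_scale, seed=int(rng.integers(2 ** 31)), **kw,
            )
        )
    return subjects


# ---------------------------------------------------------------------------
# Tabular text round-trip
# ---------------------------------------------------------------------------

_RESPONSE_COLS = [
    "voxel_id", "rv_deg", "theta_v_rad", "prf_size_deg", "class_idx",
    "beta", "sigma_vi",
]
_BOOT_COLS = ["voxel_id", "class_idx", "boot_idx", "beta_boot"]
_RUN_COLS = ["voxel_id", "class_idx", "run_idx", "amplitude"]


def write_table(subject: SyntheticSubject, outdir: str | Path) -> Path:
    """Write one subject as plain CSV tables plus a JSON sidecar.

    Produces ``<id>_responses.csv`` (one row per voxel x class),
    ``<id>_bootstraps.csv``, ``<id>_runs.csv`` and ``<id>_meta.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    V, n = subject.betas.shape
    vox = np.repeat(np.arange(V), n)
    cls = np.tile(np.arange(n), V)
    resp = pd.DataFrame(
        {
            "voxel_id": vox,
            "rv_deg": np.repeat(subject.ecc, n),
            "theta_v_rad": np.repeat(subject.angle, n),
            "prf_size_deg": np.repeat(subject.prf_size, n),
            "class_idx": cls,
            "beta": subject.betas.ravel(),
            "sigma_vi": subject.sigma_vi.ravel(),
        }
    )
    resp.to_csv(outdir / f"{subject.subject_id}_responses.csv", index=False)

    nb = subject.bootstraps.shape[1]
    boot = pd.DataFrame(
        {
            "voxel_id": np.repeat(np.arange(V), nb * n),
            "class_idx": np.tile(np.tile(np.arange(n), nb), V),
            "boot_idx": np.tile(np.repeat(np.arange(nb), n), V),
            "beta_boot": subject.bootstraps.ravel(),
        }
    )
    boot.to_csv(outdir / f"{subject.subject_id}_bootstraps.csv", index=False)

    nr = subject.n_runs
    runs = pd.DataFrame(
        {
            "voxel_id": np.repeat(np.arange(V), nr * n),
            "class_idx": np.tile(np.tile(np.arange(n), nr), V),
            "run_idx": np.tile(np.repeat(np.arange(nr), n), V),
            "amplitude": subject.run_amplitudes.ravel(),
        }
    )
    runs.to_csv(outdir / f"{subject.subject_id}_runs.csv", index=False)

    meta = {
        "subject_id": subject.subject_id,
        "noise_scale": subject.noise_scale,
        "seed": subject.seed,
        "ground_truth": (
            None if subject.ground_truth is None
            else dict(zip(
                ("sigma", "a", "b", "p1", "p2", "p3", "p4", "A1", "A2", "A3", "A4"),
                subject.ground_truth.to_array().tolist(),
            ))
        ),
    }
    (outdir / f"{subject.subject_id}_meta.json").write_text(json.dumps(meta, indent=2))
    return outdir


def _require_cols(df: pd.DataFrame, cols: list[str], name: str) -> None:
    for col in cols:
        if col not in df.columns:
            raise ValueError(f"{name} table is missing required column {col!r}")


def read_table(outdir: str | Path, subject_id: str) -> SyntheticSubject:
    """Read a subject previously written with :func:`write_table`."""
    outdir = Path(outdir)
    resp = pd.read_csv(outdir / f"{subject_id}_responses.csv")
    _require_cols(resp, _RESPONSE_COLS, "responses")
    boot = pd.read_csv(outdir / f"{subject_id}_bootstraps.csv")
    _require_cols(boot, _BOOT_COLS, "bootstraps")
    runs = pd.read_csv(outdir / f"{subject_id}_runs.csv")
    _require_cols(runs, _RUN_COLS, "runs")
    meta = json.loads((outdir / f"{subject_id}_meta.json").read_text())

    resp = resp.sort_values(["voxel_id", "class_idx"])
    vox = resp["voxel_id"].unique()
    V = len(vox)
    n = resp["class_idx"].nunique()
    per_vox = resp.drop_duplicates("voxel_id").set_index("voxel_id")
    betas = resp["beta"].to_numpy().reshape(V, n)
    sigma_vi = resp["sigma_vi"].to_numpy().reshape(V, n)

    boot = boot.sort_values(["voxel_id", "boot_idx", "class_idx"])
    nb = boot["boot_idx"].nunique()
    bootstraps = boot["beta_boot"].to_numpy().reshape(V, nb, n)

    runs = runs.sort_values(["voxel_id", "run_idx", "class_idx"])
    nr = runs["run_idx"].nunique()
    run_amplitudes = runs["amplitude"].to_numpy().reshape(V, nr, n)

    gt = meta.get("ground_truth")
    return SyntheticSubject(
        meta["subject_id"],
        per_vox.loc[vox, "rv_deg"].to_numpy(),
        per_vox.loc[vox, "theta_v_rad"].to_numpy(),
        per_vox.loc[vox, "prf_size_deg"].to_numpy(),
        betas, sigma_vi, bootstraps, run_amplitudes,
        ground_truth=None if gt is None else Model2DParams(**gt),
        noise_scale=meta["noise_scale"],
        seed=meta["seed"],
    )
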