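"""One-dimensional log-normal spatial-frequency tuning curves.

Voxels are grouped into 1-degree eccentricity bins spanning 1-12 degrees;
within each bin and for each of the four primary stimulus categories the
mean response is fit with a log-Gaussian in spatial frequency,

    beta_hat(w_l) = A * exp(-log2(w_l * p)^2 / (2 sigma^2)),

whose mode sits at w_l = 1/p (p the preferred period in degrees, sigma the
bandwidth in octaves; the full width at half maximum is 2*sqrt(2 ln 2)*sigma
octaves).  Uncertainty comes from bootstrapping across the 12 runs, and
subjects are combined with a bootstrapped precision-weighted mean

    p = sum_s(p_s / sigma_s^2) / sum_s(1 / sigma_s^2),

where sigma_s is the 16-84 percentile spread of subject s's bootstraps.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .stimulus import FrequencyVector, build_frequency_vectors
from .synth import SyntheticSubject

logger = logging.getLogger("sfmap")

__all__ = [
    "ECC_BIN_EDGES",
    "TuningCurve1D",
    "GroupEstimate",
    "TuningFitError",
    "bin_and_average",
    "fit_lognormal",
    "bootstrap_bins",
    "group_mean",
    "fit_affine",
]

#: Half-open 1-degree bins [1,2), ..., [11,12).
ECC_BIN_EDGES = np.arange(1.0, 13.0)

PRIMARY_CATEGORIES = ("pinwheel", "annulus", "forward-spiral", "reverse-spiral")


class TuningFitError(RuntimeError):
    """A tuning-curve fit failed to converge; the bin is excluded."""


@dataclass(frozen=True)
class TuningCurve1D:
    """Log-normal tuning curve: gain, preferred period (deg), bandwidth (oct)."""

    gain: float
    preferred_period: float
    bandwidth: float

    def __post_init__(self) -> None:
        if self.preferred_period <= 0 or self.bandwidth <= 0:
            raise ValueError("preferred period and bandwidth must be positive")

    @property
    def fwhm(self) -> float:
        """Full width at half maximum in octaves."""
        return 2.0 * math.sqrt(2.0 * math.log(2.0)) * self.bandwidth

    def __call__(self, omega_l) -> np.ndarray | float:
        u = np.log2(np.asarray(omega_l, dtype=float) * self.preferred_period)
        out = self.gain * np.exp(-(u ** 2) / (2 * self.bandwidth ** 2))
        return float(out) if out.ndim == 0 else out


@dataclass
class GroupEstimate:
    """Bootstrap distribution of a precision-weighted across-subject mean."""

    draws: np.ndarray

    @property
    def median(self) -> float:
        return float(np.median(self.draws))

    @property
    def ci68(self) -> tuple[float, float]:
        lo, hi = np.percentile(self.draws, [16, 84])
        return float(lo), float(hi)


def bin_and_average(
    ecc: np.ndarray,
    betas: np.ndarray,
    category: str,
    vectors: Sequence[FrequencyVector] | None = None,
    bin_edges: np.ndarray = ECC_BIN_EDGES,
) -> pd.DataFrame:
    """Mean response per eccentricity bin for one stimulus category.

    Returns a table with one row per (bin, stimulus class of the category):
    bin_center_deg, class_idx, omega_l (local frequency at the bin center,
    cycles/degree) and response (mean beta over the bin's voxels).  Empty
    bins are flagged with n_voxels = 0 and NaN responses and are excluded
    from fitting.
    """
    vectors = list(vectors) if vectors is not None else build_frequency_vectors()
    ecc = np.asarray(ecc, dtype=float)
    betas = np.asarray(betas, dtype=float)
    cls_idx = [i for i, v in enumerate(vectors) if v.category == category]
    if not cls_idx:
        raise ValueError(f"no stimulus classes with category {category!r}")
    rows = []
    for lo, hi in zip(bin_edges[:-1], bin_edges[1:]):
        center = 0.5 * (lo + hi)
        members = (ecc >= lo) & (ecc < hi)
        nvox = int(members.sum())
        if nvox == 0:
            logger.warning("empty eccentricity bin [%g, %g)", lo, hi)
        mean_beta = betas[members].mean(axis=0) if nvox else np.full(betas.shape[1], np.nan)
        for i in cls_idx:
            rows.append(
                {
                    "bin_center_deg": center,
                    "class_idx": i,
                    "omega_l": vectors[i].magnitude / (2 * math.pi * center),
                    "response": mean_beta[i],
                    "n_voxels": nvox,
                }
            )
    return pd.DataFrame(rows)


def _lognormal(omega, gain, period, bw):
    u = np.log2(omega * period)
    return gain * np.exp(-(u ** 2) / (2 * bw ** 2))


def fit_lognormal(responses: np.ndarray, frequencies: np.ndarray) -> TuningCurve1D:
    """Least-squares log-normal tuning-curve fit.

    Requires at least 4 (frequency, response) pairs spanning more than one
    octave.  Initialization: gain at the peak response, period at the
    reciprocal of the best frequency, bandwidth 2 octaves; bounds keep the
    period in [0.01, 100] degrees and the bandwidth in [0.1, 10] octaves.
    """
    responses = np.asarray(responses, dtype=float)
    frequencies = np.asarray(frequencies, dtype=float)
    ok = np.isfinite(responses) & np.isfinite(frequencies)
    responses, frequencies = responses[ok], frequencies[ok]
    if len(responses) < 4:
        raise TuningFitError("need at least 4 points for a tuning-curve fit")
    if np.log2(frequencies.max() / frequencies.min()) <= 1.0:
        raise TuningFitError("frequencies must span more than one octave")
    peak = float(np.max(responses))
    p0 = (max(peak, 1e-3), 1.0 / frequencies[np.argmax(responses)], 2.0)
    try:
        popt, _ = curve_fit(
            _lognormal, frequencies, responses, p0=p0,
            bounds=([1e-6, 0.01, 0.1], [np.inf, 100.0, 10.0]),
            maxfev=10_000,
        )
    except RuntimeError as err:  # pragma: no cover - scipy convergence failure
        raise TuningFitError(f"tuning-curve fit did not converge: {err}") from err
    return TuningCurve1D(*map(float, popt))


def bootstrap_bins(
    subject: SyntheticSubject,
    category: str,
    n_boot: int = 100,
    seed: int = 0,
    vectors: Sequence[FrequencyVector] | None = None,
    bin_edges: np.ndarray = ECC_BIN_EDGES,
    eligible: np.ndarray | None = None,
) -> pd.DataFrame:
    """Run-bootstrap distribution of tuning-curve fits per eccentricity bin.

    Each bootstrap resamples the subject's runs with replacement, recomputes
    voxel response amplitudes as resampled-run means, bin-averages, and
    refits the log-normal curve in every bin.  Returns a long table
    (bin_center_deg, boot_idx, gain, preferred_period, bandwidth, fwhm);
    failed fits are dropped, and a bin with more than 50% failures is
    flagged unreliable (column ``reliable``).
    """
    vectors = list(vectors) if vectors is not None else build_frequency_vectors()
    rng = np.random.default_rng(seed)
    n_runs = subject.n_runs
    runs = subject.run_amplitudes
    ecc = subject.ecc
    if eligible is not None:
        runs, ecc = runs[eligible], ecc[eligible]
    rows = []
    resamples = rng.integers(0, n_runs, size=(n_boot, n_runs))
    for bidx in range(n_boot):
        betas_b = runs[:, resamples[bidx], :].mean(axis=1)
        table = bin_and_average(ecc, betas_b, category, vectors, bin_edges)
        for center, grp in table.groupby("bin_center_deg"):
            if grp["n_voxels"].iloc[0] == 0:
                continue
            try:
                curve = fit_lognormal(grp["response"].to_numpy(), grp["omega_l"].to_numpy())
            except TuningFitError:
                rows.append({"bin_center_deg": center, "boot_idx": bidx, "failed": True})
                continue
            rows.append(
                {
                    "bin_center_deg": center,
                    "boot_idx": bidx,
                    "gain": curve.gain,
                    "preferred_period": curve.preferred_period,
                    "bandwidth": curve.bandwidth,
                    "fwhm": curve.fwhm,
                    "failed": False,
                }
            )
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    fail_rate = df.groupby("bin_center_deg")["failed"].mean()
    df["reliable"] = df["bin_center_deg"].map(fail_rate <= 0.5)
    for center, rate in fail_rate.items():
        if rate > 0.5:
            logger.warning("bin %g marked unreliable: %.0f%% failed fits", center, 100 * rate)
    return df[~df["failed"]].drop(columns="failed").reset_index(drop=True)


def group_mean(
    medians: np.ndarray,
    spreads: np.ndarray,
    n_boot: int = 100,
    seed: int = 0,
    n_draw: int | None = None,
) -> GroupEstimate:
    """Bootstrapped precision-weighted mean across subjects.

    ``medians`` are per-subject medians (e.g. of the preferred period over
    run bootstraps); ``spreads`` the matching 16-84 percentile ranges.  Each
    bootstrap resamples subjects with replacement and computes
    sum(m_s/sigma_s^2)/sum(1/sigma_s^2).  A zero spread would give infinite
    weight; such subjects are capped at the largest finite weight.
    """
    medians = np.asarray(medians, dtype=float)
    spreads = np.asarray(spreads, dtype=float)
    if medians.ndim != 1 or medians.shape != spreads.shape:
        raise ValueError("medians and spreads must be matching 1-d arrays")
    S = len(medians)
    if S == 1:
        return GroupEstimate(np.full(n_boot, medians[0]))
    with np.errstate(divide="ignore"):
        weights = 1.0 / spreads ** 2
    if np.any(~np.isfinite(weights)):
        finite = weights[np.isfinite(weights)]
        cap = finite.max() if finite.size else 1.0
        logger.warning("zero spread for %d subject(s); weight capped", int(np.sum(~np.isfinite(weights))))
        weights = np.where(np.isfinite(weights), weights, cap)
    rng = np.random.default_rng(seed)
    n_draw = n_draw or S
    draws = np.empty(n_boot)
    for k in range(n_boot):
        idx = rng.integers(0, S, n_draw)
        draws[k] = np.sum(medians[idx] * weights[idx]) / np.sum(weights[idx])
    return GroupEstimate(draws)


def fit_affine(bin_centers: np.ndarray, periods: np.ndarray) -> tuple[float, float]:
    """Ordinary least-squares line p(r) = slope * r + intercept."""
    bin_centers = np.asarray(bin_centers, dtype=float)
    periods = np.asarray(periods, dtype=float)
    ok = np.isfinite(periods)
    if ok.sum() < 3:
        raise ValueError("need at least 3 bins for an affine fit")
    slope, intercept = np.polyfit(bin_centers[ok], periods[ok], 1)
    return float(slope), float(intercept)
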