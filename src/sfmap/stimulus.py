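"""Log-polar grating stimuli for mapping spatial-frequency preferences.

Stimuli are sinusoidal gratings in log-polar retinal coordinates,

    f(r, theta) = cos(w_r * ln(r) + w_a * theta + phi),

where ``r`` is eccentricity in degrees of visual angle and ``theta`` the polar
angle (counterclockwise from the right horizontal meridian).  The radial
frequency ``w_r`` counts radians per unit of ln(r); the angular frequency
``w_a`` counts grating cycles per revolution.  The local spatial frequency of
such a grating is ``sqrt(w_r^2 + w_a^2) / r`` radians per degree — it falls
as 1/r, so the local period grows linearly with eccentricity, matching the
approximate scaling of spatial-frequency preferences across the visual field.
The local orientation is ``theta + atan2(w_a, w_r)``; by this convention a
value of 0 denotes a locally *vertical* grating (horizontal phase gradient).

The canonical stimulus set contains 48 frequency vectors in five categories
(pinwheel, annulus, forward spiral, reverse spiral, and fixed-frequency
mixtures), each rendered at 8 phases.
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
from scipy.interpolate import UnivariateSpline

logger = logging.getLogger("sfmap")

__all__ = [
    "FrequencyVector",
    "StimulusSpec",
    "GridSpec",
    "MTFCurve",
    "PHASES",
    "build_frequency_vectors",
    "build_stimulus_set",
    "local_frequency",
    "local_orientation",
    "render",
    "fit_mtf",
    "mtf_compensate",
    "read_mtf_csv",
    "write_stimulus_set",
]

#: The 8 phases used for every frequency vector: 0, pi/4, ..., 7*pi/4.
PHASES: tuple[float, ...] = tuple(k * math.pi / 4 for k in range(8))

_CATEGORIES = ("pinwheel", "annulus", "forward-spiral", "reverse-spiral", "mixture")

# Canonical integer frequency magnitudes of the published set.
_PINWHEEL_WA = (-6, -8, -11, -16, -23, -32, -45, -64, -91, -128)
_ANNULUS_WR = (6, 8, 11, 16, 23, 32, 45, 64, 91, 128)
_SPIRAL_W = (4, 6, 8, 11, 16, 23, 32, 45, 64, 91)
_MIXTURES = ((8, 31), (16, 28), (28, 16), (31, 8), (31, -8), (28, -16), (16, -28), (8, -31))


@dataclass(frozen=True)
class FrequencyVector:
    """One (w_r, w_a) stimulus class.

    Parameters
    ----------
    radial_freq:
        w_r, radians per unit of ln(eccentricity); signed integer.
    angular_freq:
        w_a, grating cycles per revolution; signed integer.
    category:
        One of {"pinwheel", "annulus", "forward-spiral", "reverse-spiral",
        "mixture"}.  Pinwheels have w_r = 0, annuli w_a = 0, forward spirals
        w_r = -w_a, reverse spirals w_r = w_a.
    """

    radial_freq: int
    angular_freq: int
    category: str

    def __post_init__(self) -> None:
        if (self.radial_freq, self.angular_freq) == (0, 0):
            raise ValueError("frequency vector (0, 0) is not a stimulus")
        if self.category not in _CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")

    @property
    def magnitude(self) -> float:
        """Base frequency sqrt(w_r^2 + w_a^2), radians per unit ln(r)."""
        return math.hypot(self.radial_freq, self.angular_freq)


@dataclass(frozen=True)
class StimulusSpec:
    """A frequency vector at one of the 8 phases (radians)."""

    vector: FrequencyVector
    phase: float


@dataclass(frozen=True)
class GridSpec:
    """Pixel grid and retinal-coordinate mapping for rendered stimuli.

    The display subtended a 12 degree radius with a small anti-aliasing mask
    at the center; both are configurable here.  The default grid is
    1536 x 1536 pixels at 64 px/degree.
    """

    image_side: int = 1536
    pixels_per_degree: float = 64.0
    max_eccentricity: float = 12.0
    inner_mask_radius: float = 0.96
    ramp_width: float = 0.5  # raised-cosine ramp at both mask edges, degrees

    def __post_init__(self) -> None:
        if self.max_eccentricity * self.pixels_per_degree > self.image_side / 2 + 1e-9:
            raise ValueError("max_eccentricity does not fit on the pixel grid")
        if not self.inner_mask_radius < self.max_eccentricity:
            raise ValueError("inner_mask_radius must be below max_eccentricity")

    def retinal_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (r, theta) maps in degrees / radians for every pixel.

        theta is measured counterclockwise from the right horizontal
        meridian, with the vertical axis pointing up (math convention).
        """
        c = (self.image_side - 1) / 2.0
        idx = np.arange(self.image_side)
        x = (idx - c) / self.pixels_per_degree
        y = (c - idx) / self.pixels_per_degree  # row 0 is the top of the image
        xx, yy = np.meshgrid(x, y)
        r = np.hypot(xx, yy)
        theta = np.arctan2(yy, xx)
        return r, theta


def build_frequency_vectors() -> list[FrequencyVector]:
    """Return the canonical 48 frequency vectors in their five categories."""
    vectors: list[FrequencyVector] = []
    vectors += [FrequencyVector(0, wa, "pinwheel") for wa in _PINWHEEL_WA]
    vectors += [FrequencyVector(wr, 0, "annulus") for wr in _ANNULUS_WR]
    vectors += [FrequencyVector(w, -w, "forward-spiral") for w in _SPIRAL_W]
    vectors += [FrequencyVector(w, w, "reverse-spiral") for w in _SPIRAL_W]
    vectors += [FrequencyVector(wr, wa, "mixture") for wr, wa in _MIXTURES]
    assert len(vectors) == 48
    return vectors


def build_stimulus_set() -> list[StimulusSpec]:
    """Return the full set of 48 vectors x 8 phases = 384 stimulus specs."""
    return [StimulusSpec(v, phi) for v in build_frequency_vectors() for phi in PHASES]


def local_frequency(vector: FrequencyVector, r) -> np.ndarray | float:
    """Local spatial frequency in cycles/degree at eccentricity ``r`` (deg).

    Equal to the Euclidean norm of the frequency vector divided by the
    eccentricity (radians/degree), converted to cycles/degree.  Independent
    of polar angle.  Undefined at the fovea (r = 0).
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("local frequency is undefined for r <= 0")
    out = vector.magnitude / (2.0 * math.pi * r)
    return float(out) if out.ndim == 0 else out


def local_orientation(vector: FrequencyVector, theta) -> np.ndarray | float:
    """Local orientation in radians, reduced mod pi.

    This is the angle of the phase-gradient (frequency) vector,
    counterclockwise from horizontal: ``(theta + atan2(w_a, w_r)) mod pi``.
    A value of 0 denotes a locally vertical grating.
    """
    theta = np.asarray(theta, dtype=float)
    out = np.mod(theta + math.atan2(vector.angular_freq, vector.radial_freq), math.pi)
    return float(out) if out.ndim == 0 else out


def _raised_cosine_envelope(r: np.ndarray, grid: GridSpec) -> np.ndarray:
    """Amplitude envelope: 0 inside the central mask and outside the
    aperture, with raised-cosine ramps of ``grid.ramp_width`` degrees."""
    w = grid.ramp_width
    lo, hi = grid.inner_mask_radius, grid.max_eccentricity
    env = np.zeros_like(r)
    rising = (r >= lo) & (r < lo + w)
    env[rising] = 0.5 * (1 - np.cos(np.pi * (r[rising] - lo) / w))
    env[(r >= lo + w) & (r <= hi - w)] = 1.0
    falling = (r > hi - w) & (r <= hi)
    env[falling] = 0.5 * (1 - np.cos(np.pi * (hi - r[falling]) / w))
    return env


def render(spec: StimulusSpec, grid: GridSpec, masked: bool = True) -> np.ndarray:
    """Render a stimulus on the pixel grid, in signed units (mid-gray = 0).

    With ``masked=True`` (default) the central mask and the region outside
    the aperture are set to 0 and a raised-cosine amplitude ramp is applied
    at both mask edges.  With ``masked=False`` the raw cosine carrier is
    returned everywhere (the foveal pixel, where ln r diverges, is set to 0).
    """
    r, theta = grid.retinal_coords()
    v = spec.vector
    with np.errstate(divide="ignore", invalid="ignore"):
        phase_map = v.radial_freq * np.log(r) + v.angular_freq * theta + spec.phase
    img = np.cos(phase_map)
    img[~np.isfinite(img)] = 0.0
    if masked:
        img *= _raised_cosine_envelope(r, grid)
    return img


# ---------------------------------------------------------------------------
# Display MTF measurement and compensation
# ---------------------------------------------------------------------------

@dataclass
class MTFCurve:
    """Fitted modulation transfer function of a display.

    Michelson contrast as a smooth function of spatial frequency in
    cycles/pixel; evaluable on the sampled frequency range, clamped (with a
    logged warning) outside it and clipped to (0, 1].
    """

    frequencies: np.ndarray  # cycles/pixel, ascending
    contrasts: np.ndarray
    spline: UnivariateSpline = field(repr=False)

    @property
    def domain(self) -> tuple[float, float]:
        return float(self.frequencies[0]), float(self.frequencies[-1])

    def __call__(self, freq) -> np.ndarray | float:
        freq = np.asarray(freq, dtype=float)
        lo, hi = self.domain
        if np.any((freq < lo) | (freq > hi)):
            logger.warning(
                "MTF evaluated outside sampled range [%.4g, %.4g] cycles/pixel; clamping",
                lo, hi,
            )
        clamped = np.clip(freq, lo, hi)
        out = np.clip(self.spline(clamped), 1e-6, 1.0)
        return float(out) if out.ndim == 0 else out


def fit_mtf(samples: Sequence[tuple[float, float]], smoothing: float = 1e-3) -> MTFCurve:
    """Fit a degree-1 smoothing spline to MTF measurements.

    Parameters
    ----------
    samples:
        Pairs of (grating period in pixels, Michelson contrast in (0, 1]).
        Periods of 2 pixels correspond to the display Nyquist frequency of
        0.5 cycles/pixel.
    smoothing:
        Smoothing factor ``s`` of the spline (sum-of-squared-residual
        budget); small because contrasts live on [0, 1].
    """
    samples = list(samples)
    if len(samples) < 4:
        raise ValueError("need at least 4 MTF samples to fit a spline")
    periods = np.asarray([p for p, _ in samples], dtype=float)
    contrasts = np.asarray([c for _, c in samples], dtype=float)
    if np.any(periods <= 0):
        raise ValueError("periods must be positive (pixels)")
    if np.any((contrasts <= 0) | (contrasts > 1)):
        raise ValueError("contrasts must lie in (0, 1]")
    freqs = 1.0 / periods
    order = np.argsort(freqs)
    freqs, contrasts = freqs[order], contrasts[order]
    spline = UnivariateSpline(freqs, contrasts, k=1, s=smoothing)
    return MTFCurve(freqs, contrasts, spline)


def mtf_compensate(
    image: np.ndarray, spec: StimulusSpec, grid: GridSpec, mtf: MTFCurve
) -> np.ndarray:
    """Pre-compensate a rendered stimulus for display blur.

    The amplitude at each eccentricity is scaled by
    ``mtf(local frequency) / max(mtf over the image's frequency range)``,
    i.e. low-frequency content (which the display reproduces faithfully) is
    attenuated relative to the worst-reproduced frequency so that the
    *displayed* contrast is equalized across eccentricity without the
    compensated amplitude ever exceeding the input amplitude.
    """
    r, _ = grid.retinal_coords()
    active = (r >= grid.inner_mask_radius) & (r <= grid.max_eccentricity)
    # local frequency in cycles/pixel at every active pixel
    cpd = spec.vector.magnitude / (2.0 * math.pi * np.where(active, r, np.nan))
    cpp = cpd / grid.pixels_per_degree
    fvals = cpp[active]
    attained = mtf(np.linspace(fvals.min(), fvals.max(), 256))
    scale = float(np.max(attained))
    envelope = np.ones_like(image)
    envelope[active] = np.asarray(mtf(fvals)) / scale
    return image * envelope


# ---------------------------------------------------------------------------
# External interfaces
# ---------------------------------------------------------------------------

def read_mtf_csv(path: str | Path) -> MTFCurve:
    """Read MTF measurements (columns period_pixels, michelson_contrast)."""
    df = pd.read_csv(path)
    for col in ("period_pixels", "michelson_contrast"):
        if col not in df.columns:
            raise ValueError(f"MTF csv missing required column {col!r}")
    return fit_mtf(list(zip(df["period_pixels"], df["michelson_contrast"])))


def write_stimulus_set(
    outdir: str | Path,
    grid: GridSpec | None = None,
    mtf: MTFCurve | None = None,
    specs: Sequence[StimulusSpec] | None = None,
) -> pd.DataFrame:
    """Render the stimulus set to 8-bit grayscale PNGs with a sidecar table.

    Writes ``stim_<index>.png`` per spec, ``stimuli.csv`` with columns
    (index, category, w_r, w_a, phase) and ``grid.json`` recording the grid.
    Returns the sidecar table.
    """
    from PIL import Image

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    grid = grid or GridSpec()
    specs = list(specs) if specs is not None else build_stimulus_set()
    rows = []
    for i, spec in enumerate(specs):
        img = render(spec, grid)
        if mtf is not None:
            img = mtf_compensate(img, spec, grid, mtf)
        u8 = np.round((np.clip(img, -1, 1) + 1) * 127.5).astype(np.uint8)
        Image.fromarray(u8, mode="L").save(outdir / f"stim_{i:03d}.png")
        rows.append(
            {
                "index": i,
                "category": spec.vector.category,
                "w_r": spec.vector.radial_freq,
                "w_a": spec.vector.angular_freq,
                "phase": spec.phase,
            }
        )
    table = pd.DataFrame(rows)
    table.to_csv(outdir / "stimuli.csv", index=False)
    meta = {
        "image_side": grid.image_side,
        "pixels_per_degree": grid.pixels_per_degree,
        "max_eccentricity": grid.max_eccentricity,
        "inner_mask_radius": grid.inner_mask_radius,
        "ramp_width": grid.ramp_width,
    }
    (outdir / "grid.json").write_text(json.dumps(meta, indent=2))
    return table
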