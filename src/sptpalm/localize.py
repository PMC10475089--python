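"""Spot detection and sub-pixel 2D Gaussian localization.

Candidate spots are local maxima of a band-pass (difference-of-Gaussians)
filtered frame exceeding a robust threshold; each candidate is then fit by
a symmetric, pixel-integrated 2D Gaussian whose centre is taken as the
particle position.

Coordinate convention (stated in all output headers): pixels are indexed
0-based by (row i, col j); the centre of pixel (i, j) is at
``x = (j + 0.5) * pixel_size``, ``y = (i + 0.5) * pixel_size`` in nm.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, optimize
from scipy.special import erf
from skimage.feature import peak_local_max

__all__ = [
    "ImagingConfig",
    "Localization",
    "RejectionLog",
    "detect_candidates",
    "fit_spot",
    "localize_movie",
]

logger = logging.getLogger(__name__)

LOCALIZATION_COLUMNS = [
    "frame",
    "x_nm",
    "y_nm",
    "amplitude",
    "sigma_nm",
    "offset",
    "residual_rms",
]


@dataclass(frozen=True)
class ImagingConfig:
    """Acquisition and fitting parameters."""

    pixel_size: float = 160.0  # nm
    frame_interval: float = 0.1  # s
    detection_threshold: float = 5.0  # multiples of robust background SD
    fit_window: int = 7  # pixels, odd
    dog_sigma_low: float = 1.0  # px, band-pass inner scale
    dog_sigma_high: float = 3.0  # px, band-pass outer scale
    sigma_bounds_px: tuple[float, float] = (0.3, 3.0)

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.fit_window < 5 or self.fit_window % 2 == 0:
            raise ValueError("fit_window must be odd and >= 5")


@dataclass(frozen=True)
class Localization:
    frame: int
    x_nm: float
    y_nm: float
    amplitude: float  # fitted total signal counts
    sigma_nm: float
    offset: float
    residual_rms: float
    cell_id: int | None = None


@dataclass
class RejectionLog:
    """Counts of candidates that produced no localization, by cause."""

    edge: int = 0
    non_convergence: int = 0
    sigma_out_of_range: int = 0

    def total(self) -> int:
        return self.edge + self.non_convergence + self.sigma_out_of_range


def _robust_sd(image: np.ndarray) -> float:
    med = np.median(image)
    return 1.4826 * float(np.median(np.abs(image - med)))


def detect_candidates(frame: np.ndarray, cfg: ImagingConfig) -> np.ndarray:
    """Integer (row, col) candidate positions in one frame.

    Local maxima of the DoG-filtered frame above
    ``detection_threshold * robust SD``; maxima closer than ``fit_window``
    pixels are merged to the brighter one.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise ValueError("detect_candidates expects a single 2D frame")
    dog = ndimage.gaussian_filter(frame, cfg.dog_sigma_low) - ndimage.gaussian_filter(
        frame, cfg.dog_sigma_high
    )
    sd = _robust_sd(dog)
    if sd == 0.0:
        return np.empty((0, 2), dtype=int)
    # min_distance merges maxima closer than fit_window, keeping the brighter
    peaks = peak_local_max(
        dog,
        min_distance=cfg.fit_window,
        threshold_abs=cfg.detection_threshold * sd,
        exclude_border=False,
    )
    if len(peaks) < 2:
        return peaks
    return peaks[np.lexsort((peaks[:, 1], peaks[:, 0]))]


def _integrated_gaussian_window(
    size: int, x0: float, y0: float, sigma: float
) -> np.ndarray:
    """Unit-flux pixel-integrated Gaussian over a size×size window.

    Coordinates are in pixel units relative to the window origin; pixel
    (i, j) spans [j, j+1) × [i, i+1).
    """
    s = sigma * math.sqrt(2.0)
    e = np.arange(size + 1, dtype=float)
    fx = 0.5 * (erf((e[1:] - x0) / s) - erf((e[:-1] - x0) / s))
    fy = 0.5 * (erf((e[1:] - y0) / s) - erf((e[:-1] - y0) / s))
    return np.outer(fy, fx)


def _spot_objective(window: np.ndarray):
    size = window.shape[0]
    flat = window.ravel()

    def residuals(params: np.ndarray) -> np.ndarray:
        amp, x0, y0, sigma, offset = params
        model = amp * _integrated_gaussian_window(size, x0, y0, sigma) + offset
        return model.ravel() - flat

    return residuals


def fit_spot(
    frame: np.ndarray,
    candidate: tuple[int, int],
    cfg: ImagingConfig,
    frame_index: int = 0,
    log: RejectionLog | None = None,
) -> Localization | None:
    """Least-squares fit of a symmetric integrated 2D Gaussian plus offset.

    Returns ``None`` (and counts the cause in ``log``) when the candidate is
    too close to the frame edge, the fit does not converge, or the fitted
    sigma falls outside ``sigma_bounds_px``.
    """
    frame = np.asarray(frame, dtype=float)
    i, j = int(candidate[0]), int(candidate[1])
    half = cfg.fit_window // 2
    h, w = frame.shape
    if i < half or j < half or i >= h - half or j >= w - half:
        if log is not None:
            log.edge += 1
        logger.debug("candidate (%d, %d) skipped: within %d px of edge", i, j, half)
        return None
    window = frame[i - half : i + half + 1, j - half : j + half + 1]
    size = cfg.fit_window

    offset0 = float(window.min())
    amp0 = max(float(window.sum() - offset0 * size * size), 1e-3)
    yy, xx = np.mgrid[0:size, 0:size]
    weight = np.clip(window - offset0, 0, None)
    wsum = weight.sum()
    if wsum > 0:
        x0 = float((weight * (xx + 0.5)).sum() / wsum)
        y0 = float((weight * (yy + 0.5)).sum() / wsum)
    else:
        x0 = y0 = size / 2.0
    p0 = np.array([amp0, x0, y0, 1.0, offset0])

    lo, hi = cfg.sigma_bounds_px
    try:
        result = optimize.least_squares(
            _spot_objective(window),
            p0,
            bounds=(
                [0.0, -1.0, -1.0, 0.5 * lo, -np.inf],
                [np.inf, size + 1.0, size + 1.0, 2.0 * hi, np.inf],
            ),
            method="trf",
            xtol=1e-10,
            ftol=1e-10,
        )
    except Exception:
        if log is not None:
            log.non_convergence += 1
        return None
    if not result.success:
        if log is not None:
            log.non_convergence += 1
        return None
    amp, x0, y0, sigma, offset = result.x
    if not (lo <= sigma <= hi):
        if log is not None:
            log.sigma_out_of_range += 1
        return None
    # window-local pixel edges -> global physical nm (half-pixel centre
    # convention: the centre of pixel (i, j) is ((j+0.5)a, (i+0.5)a))
    x_nm = (j - half + x0) * cfg.pixel_size
    y_nm = (i - half + y0) * cfg.pixel_size
    rms = float(np.sqrt(np.mean(result.fun**2)))
    return Localization(
        frame=frame_index,
        x_nm=float(x_nm),
        y_nm=float(y_nm),
        amplitude=float(amp),
        sigma_nm=float(sigma * cfg.pixel_size),
        offset=float(offset),
        residual_rms=rms,
    )


def localize_movie(
    stack: np.ndarray,
    cfg: ImagingConfig | None = None,
    log: RejectionLog | None = None,
) -> pd.DataFrame:
    """Detect and fit spots in every frame of a stack.

    Returns a tidy table with columns ``frame, x_nm, y_nm, amplitude,
    sigma_nm, offset, residual_rms`` — deterministic given its inputs.
    """
    cfg = cfg or ImagingConfig()
    stack = np.asarray(stack)
    if stack.size and stack.ndim != 3:
        raise ValueError("expected a stack of 2D frames")
    rows = []
    for f, frame in enumerate(stack):
        for cand in detect_candidates(frame, cfg):
            loc = fit_spot(frame, cand, cfg, frame_index=f, log=log)
            if loc is not None:
                rows.append(loc)
    if not rows:
        return pd.DataFrame(columns=LOCALIZATION_COLUMNS)
    df = pd.DataFrame([loc.__dict__ for loc in rows])[LOCALIZATION_COLUMNS]
    return df
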