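"""Per-track mobility classification and diffusion analysis.

A retained track is classified immobile when the axis-aligned bounding box
of its positions fits inside one camera pixel (both sides < 160 nm).
Mobile tracks get a time-averaged MSD (TAMSD); the anomalous exponent α is
the slope of log TAMSD vs log lag over the first four lags
(log TAMSD = log 4D + α log Δt), tracks with α outside [0, 1.5] are
excluded as non-diffusive, and the diffusion coefficient D comes from a
straight-line fit of TAMSD to the first four lags (MSD = 4DΔt) with a free
intercept that absorbs the constant 4σ² static-localization-error offset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TAMSDCurve",
    "MotionResult",
    "classify_mobility",
    "tamsd",
    "fit_anomalous",
    "filter_alpha",
    "fit_diffusion_coefficient",
    "analyze_tracks",
]

DEFAULT_BOX_SIZE_NM = 160.0
DEFAULT_ALPHA_BOUNDS = (0.0, 1.5)
N_FIT_LAGS = 4

MOTION_COLUMNS = [
    "track_id",
    "n_frames",
    "mobility",
    "alpha",
    "D_um2_s",
    "alpha_in_range",
    "negative_D",
    "exclusion_cause",
]


@dataclass(frozen=True)
class TAMSDCurve:
    """Time-averaged MSD of one track.

    ``lags`` are multiples of the frame interval in seconds, ``values`` the
    mean squared planar displacement at each lag in µm², and
    ``n_pairs_per_lag`` the number of overlapping position pairs averaged.
    """

    lags: np.ndarray
    values: np.ndarray
    n_pairs_per_lag: np.ndarray


@dataclass(frozen=True)
class MotionResult:
    track_id: int
    n_frames: int
    mobility: str  # "immobile" | "mobile" | "excluded"
    alpha: float = np.nan
    D: float = np.nan  # µm²/s
    alpha_in_range: bool = False
    negative_D: bool = False
    exclusion_cause: str = ""


def classify_mobility(xy_nm: np.ndarray, box_size: float = DEFAULT_BOX_SIZE_NM) -> str:
    """Immobile iff the bounding box of all positions has both side
    lengths strictly below ``box_size`` (one pixel)."""
    xy = np.atleast_2d(np.asarray(xy_nm, dtype=float))
    span = xy.max(axis=0) - xy.min(axis=0)
    return "immobile" if bool(np.all(span < box_size)) else "mobile"


def tamsd(xy_nm: np.ndarray, frame_interval: float) -> TAMSDCurve:
    """Time-averaged MSD over all overlapping pairs at each lag.

    Positions are consecutive-frame localizations in nm; values are
    returned in µm².  Lags run from 1 to ``n_frames - 1`` frame intervals.
    """
    xy = np.asarray(xy_nm, dtype=float) / 1000.0  # nm -> µm
    n = len(xy)
    if n < 2:
        return TAMSDCurve(np.empty(0), np.empty(0), np.empty(0, dtype=int))
    lags = np.arange(1, n)
    values = np.empty(n - 1)
    pairs = np.empty(n - 1, dtype=int)
    for k in lags:
        d = xy[k:] - xy[:-k]
        values[k - 1] = np.mean(np.einsum("ij,ij->i", d, d))
        pairs[k - 1] = n - k
    return TAMSDCurve(lags * frame_interval, values, pairs)


def fit_anomalous(curve: TAMSDCurve) -> tuple[float, float]:
    """Anomalous-exponent fit log TAMSD = log 4D + α log Δt over the first
    four lags (ordinary least squares in log-log space).

    Raises ``ValueError`` when fewer than four lags exist or any of the
    first four TAMSD values is non-positive (the log is then undefined).
    """
    if len(curve.lags) < N_FIT_LAGS:
        raise ValueError("anomalous fit needs at least 4 lags")
    y = curve.values[:N_FIT_LAGS]
    if np.any(y <= 0):
        raise ValueError("non-positive TAMSD value; log-log fit undefined")
    alpha, intercept = np.polyfit(np.log(curve.lags[:N_FIT_LAGS]), np.log(y), 1)
    return float(alpha), float(np.exp(intercept) / 4.0)


def filter_alpha(
    alpha: float, bounds: tuple[float, float] = DEFAULT_ALPHA_BOUNDS
) -> bool:
    """True when α lies in the diffusive retention range (inclusive)."""
    return bounds[0] <= alpha <= bounds[1]


def fit_diffusion_coefficient(
    curve: TAMSDCurve, through_origin: bool = False
) -> float:
    """D from a straight-line fit of TAMSD to the first four lags
    (MSD = 4DΔt), slope / 4.

    By default the intercept is free so the static localization-error
    offset (4σ²) does not bias D; ``through_origin=True`` gives the
    no-intercept variant.  D may come out non-positive for noise-dominated
    tracks; callers flag but keep such tracks.
    """
    if len(curve.lags) < N_FIT_LAGS:
        raise ValueError("diffusion fit needs at least 4 lags")
    t = curve.lags[:N_FIT_LAGS]
    y = curve.values[:N_FIT_LAGS]
    if through_origin:
        slope = float(np.dot(t, y) / np.dot(t, t))
    else:
        slope = float(np.polyfit(t, y, 1)[0])
    return slope / 4.0


def analyze_tracks(
    tracks: pd.DataFrame,
    frame_interval: float = 0.1,
    box_size: float = DEFAULT_BOX_SIZE_NM,
    alpha_bounds: tuple[float, float] = DEFAULT_ALPHA_BOUNDS,
    through_origin: bool = False,
) -> pd.DataFrame:
    """Classify and fit every track; output order follows input order.

    Pipeline per track: bounding-box mobility classification; immobile
    tracks bypass all fitting.  Mobile tracks get TAMSD → α fit → α
    retention filter → D fit.  Mobile tracks that cannot be fit (fewer than
    four lags, or a zero TAMSD value) or whose α falls outside the
    retention range are marked ``excluded`` with the cause recorded.

    Returns a table with columns ``track_id, n_frames, mobility, alpha,
    D_um2_s, alpha_in_range, negative_D, exclusion_cause``.
    """
    rows: list[MotionResult] = []
    for tid, grp in tracks.groupby("track_id", sort=True):
        xy = grp.sort_values("frame")[["x_nm", "y_nm"]].to_numpy(dtype=float)
        n = len(xy)
        if classify_mobility(xy, box_size) == "immobile":
            rows.append(MotionResult(int(tid), n, "immobile"))
            continue
        curve = tamsd(xy, frame_interval)
        try:
            alpha, _ = fit_anomalous(curve)
        except ValueError as err:
            cause = (
                "too_few_lags" if len(curve.lags) < N_FIT_LAGS else "zero_tamsd"
            )
            rows.append(
                MotionResult(int(tid), n, "excluded", exclusion_cause=cause)
            )
            continue
        in_range = filter_alpha(alpha, alpha_bounds)
        D = fit_diffusion_coefficient(curve, through_origin=through_origin)
        if not in_range:
            rows.append(
                MotionResult(
                    int(tid),
                    n,
                    "excluded",
                    alpha=alpha,
                    D=D,
                    alpha_in_range=False,
                    negative_D=D <= 0,
                    exclusion_cause="alpha_out_of_range",
                )
            )
        else:
            rows.append(
                MotionResult(
                    int(tid),
                    n,
                    "mobile",
                    alpha=alpha,
                    D=D,
                    alpha_in_range=True,
                    negative_D=D <= 0,
                )
            )
    df = pd.DataFrame(
        [
            {
                "track_id": r.track_id,
                "n_frames": r.n_frames,
                "mobility": r.mobility,
                "alpha": r.alpha,
                "D_um2_s": r.D,
                "alpha_in_range": r.alpha_in_range,
                "negative_D": r.negative_D,
                "exclusion_cause": r.exclusion_cause,
            }
            for r in rows
        ],
        columns=MOTION_COLUMNS,
    )
    return df
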