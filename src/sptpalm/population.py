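"""Per-condition population summaries with bootstrap uncertainty.

The bootstrap unit is the single-particle track: 1000 resamples with
replacement give the mean and SD of the immobile fraction (over all
retained tracks) and of the mean mobile diffusion coefficient (over mobile,
α-retained tracks).  Two condition means are called significantly different
when they differ by more than 0.005 in the statistic's native units — the
one rule applied to both fractions and D values.  A basic one-way ANOVA is
included for cell-morphometry comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PopulationSummary",
    "ComparisonResult",
    "bootstrap_mean_sd",
    "significant_difference",
    "one_way_anova",
    "summarize_condition",
]

SIGNIFICANCE_THRESHOLD = 0.005
DEFAULT_N_BOOT = 1000


@dataclass(frozen=True)
class PopulationSummary:
    condition_label: str
    n_tracks: int
    n_immobile: int
    n_mobile: int
    immobile_fraction: float
    boot_sd_fraction: float
    mean_D_mobile: float  # µm²/s; NaN when no mobile tracks
    boot_sd_D: float
    n_boot: int = DEFAULT_N_BOOT
    seed: int | None = None


@dataclass(frozen=True)
class ComparisonResult:
    condition_a: str
    condition_b: str
    statistic: str
    difference: float
    threshold: float = SIGNIFICANCE_THRESHOLD

    @property
    def significant(self) -> bool:
        return abs(self.difference) > self.threshold


def bootstrap_mean_sd(
    values: Sequence[float] | np.ndarray,
    statistic: Callable[[np.ndarray], float] = np.mean,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int | np.random.Generator | None = None,
) -> tuple[float, float]:
    """Bootstrap mean and SD of ``statistic`` over per-track values.

    Tracks (not displacements) are resampled with replacement ``n_boot``
    times; deterministic for a given seed.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise ValueError("bootstrap needs at least 2 tracks")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.integers(0, len(values), size=(n_boot, len(values)))
    reps = np.apply_along_axis(statistic, 1, values[idx])
    return float(reps.mean()), float(reps.std(ddof=0))


def significant_difference(
    a: PopulationSummary,
    b: PopulationSummary,
    statistic: str,
    threshold: float = SIGNIFICANCE_THRESHOLD,
) -> ComparisonResult:
    """Apply the fixed-threshold significance rule to two summaries.

    ``statistic`` is ``"immobile_fraction"`` or ``"mean_D_mobile"``; the
    difference of condition means is compared with the threshold in native
    units (dimensionless fraction, or µm²/s).
    """
    if statistic not in ("immobile_fraction", "mean_D_mobile"):
        raise ValueError(f"unknown statistic {statistic!r}")
    diff = getattr(a, statistic) - getattr(b, statistic)
    return ComparisonResult(a.condition_label, b.condition_label, statistic, float(diff), threshold)


def one_way_anova(*groups: Sequence[float]) -> tuple[float, float]:
    """Classical one-way ANOVA (between/within decomposition) F and p."""
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) < 2 for g in arrays):
        raise ValueError("every group needs at least 2 values")
    f, p = stats.f_oneway(*arrays)
    return float(f), float(p)


def summarize_condition(
    motion_results: pd.DataFrame,
    label: str,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int | None = None,
) -> PopulationSummary:
    """One-row population summary of an ``analyze_tracks`` table.

    The immobile fraction is taken over all retained tracks (immobile +
    mobile + excluded); the mean D over mobile, α-retained tracks.  Both
    carry bootstrap SDs over tracks.
    """
    if motion_results.empty:
        raise ValueError("no tracks to summarize")
    rng = np.random.default_rng(seed)
    is_immobile = (motion_results["mobility"] == "immobile").to_numpy(dtype=float)
    n_immobile = int(is_immobile.sum())
    frac = float(is_immobile.mean())
    if len(is_immobile) >= 2:
        _, sd_frac = bootstrap_mean_sd(is_immobile, np.mean, n_boot, rng)
    else:
        sd_frac = 0.0
    mobile_D = motion_results.loc[
        motion_results["mobility"] == "mobile", "D_um2_s"
    ].to_numpy(dtype=float)
    if len(mobile_D) == 0:
        import warnings

        warnings.warn(f"condition {label!r} has no mobile tracks", stacklevel=2)
        mean_D, sd_D = float("nan"), float("nan")
    elif len(mobile_D) == 1:
        mean_D, sd_D = float(mobile_D[0]), 0.0
    else:
        mean_D = float(mobile_D.mean())
        _, sd_D = bootstrap_mean_sd(mobile_D, np.mean, n_boot, rng)
    return PopulationSummary(
        condition_label=label,
        n_tracks=len(motion_results),
        n_immobile=n_immobile,
        n_mobile=len(mobile_D),
        immobile_fraction=frac,
        boot_sd_fraction=sd_frac,
        mean_D_mobile=mean_D,
        boot_sd_D=sd_D,
        n_boot=n_boot,
        seed=seed,
    )
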