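"""Model/Results interface over the per-track mobility analysis.

``MobilityModel`` is built from a tidy track table and frozen analysis
settings; ``fit()`` runs classification, TAMSD fitting and bootstrap
aggregation and returns a ``MobilityResults`` object carrying the per-track
estimates, the population summary with bootstrap SDs, and a ``summary()``
text table, in the spirit of statsmodels' model/results split.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import motion, population, tracking
from .population import ComparisonResult, PopulationSummary

__all__ = ["MobilityModel", "MobilityResults"]


class MobilityModel:
    """Per-track mobility model for single-particle tracks.

    Parameters
    ----------
    tracks : DataFrame
        Tidy track table with columns ``track_id, frame, x_nm, y_nm``.
    frame_interval : float
        Acquisition interval in seconds (default 0.1 s, 10 Hz).
    box_size : float
        Immobile bounding-box criterion in nm (default one 160 nm pixel).
    alpha_bounds : tuple
        Inclusive retention range for the anomalous exponent.
    min_frames, max_frames : int
        Track-length retention window (localizations per track).
    apply_length_filter : bool
        Apply the retention window before analysis (on by default; switch
        off when the input tracks are already filtered).
    """

    def __init__(
        self,
        tracks: pd.DataFrame,
        frame_interval: float = 0.1,
        box_size: float = motion.DEFAULT_BOX_SIZE_NM,
        alpha_bounds: tuple[float, float] = motion.DEFAULT_ALPHA_BOUNDS,
        min_frames: int = 4,
        max_frames: int = 12,
        apply_length_filter: bool = True,
        through_origin: bool = False,
    ) -> None:
        required = {"track_id", "frame", "x_nm", "y_nm"}
        missing = required - set(tracks.columns)
        if missing:
            raise ValueError(f"track table missing columns: {sorted(missing)}")
        self.frame_interval = frame_interval
        self.box_size = box_size
        self.alpha_bounds = alpha_bounds
        self.min_frames = min_frames
        self.max_frames = max_frames
        self.through_origin = through_origin
        if apply_length_filter:
            filtered = tracking.filter_track_lengths(tracks, min_frames, max_frames)
            self.tracks = filtered.tracks
            self.n_too_short = filtered.n_too_short
            self.n_too_long = filtered.n_too_long
        else:
            self.tracks = tracks.reset_index(drop=True)
            self.n_too_short = self.n_too_long = 0

    @classmethod
    def from_localizations(
        cls,
        localizations: pd.DataFrame,
        max_link_distance: float = tracking.DEFAULT_LINK_DISTANCE_NM,
        **kwargs,
    ) -> "MobilityModel":
        """Build the model from an unlinked localization table."""
        return cls(tracking.link_localizations(localizations, max_link_distance), **kwargs)

    def fit(
        self,
        label: str = "condition",
        n_boot: int = population.DEFAULT_N_BOOT,
        seed: int | None = None,
    ) -> "MobilityResults":
        per_track = motion.analyze_tracks(
            self.tracks,
            frame_interval=self.frame_interval,
            box_size=self.box_size,
            alpha_bounds=self.alpha_bounds,
            through_origin=self.through_origin,
        )
        summary = population.summarize_condition(per_track, label, n_boot, seed)
        return MobilityResults(self, per_track, summary)


@dataclass
class MobilityResults:
    """Fitted per-track mobility estimates and population summary."""

    model: MobilityModel
    per_track: pd.DataFrame
    population: PopulationSummary

    @property
    def immobile_fraction(self) -> float:
        return self.population.immobile_fraction

    @property
    def mean_D_mobile(self) -> float:
        return self.population.mean_D_mobile

    def compare(self, other: "MobilityResults", statistic: str) -> ComparisonResult:
        """Fixed-threshold significance comparison with another condition."""
        return population.significant_difference(
            self.population, other.population, statistic
        )

    def plot_diagnostics(self, ax=None):
        """Scatter of per-track α vs D, coloured by mobility class, with
        the α retention band shaded."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 4))
        lo, hi = self.model.alpha_bounds
        ax.axvspan(lo, hi, color="0.92", zorder=0, label=f"α ∈ [{lo}, {hi}]")
        for cls, color in (("mobile", "tab:blue"), ("excluded", "tab:red")):
            sel = self.per_track["mobility"] == cls
            ax.scatter(
                self.per_track.loc[sel, "alpha"],
                self.per_track.loc[sel, "D_um2_s"],
                s=8,
                alpha=0.5,
                color=color,
                label=cls,
            )
        ax.set_xlabel("anomalous exponent α")
        ax.set_ylabel("D (µm²/s)")
        ax.legend(frameon=False, fontsize=8)
        ax.set_title(f"{self.population.condition_label}: per-track TAMSD fits")
        return ax

    def summary(self) -> str:
        p = self.population
        n_excl = int((self.per_track["mobility"] == "excluded").sum())
        lines = [
            "Single-particle mobility summary",
            "=" * 46,
            f"condition:            {p.condition_label}",
            f"tracks retained:      {p.n_tracks}"
            f"  (rejected: {self.model.n_too_short} short, {self.model.n_too_long} long)",
            f"immobile:             {p.n_immobile}"
            f"  fraction {p.immobile_fraction:.3f} ± {p.boot_sd_fraction:.3f} (bootstrap)",
            f"mobile (α-retained):  {p.n_mobile}",
            f"excluded (α/fit):     {n_excl}",
            f"mean D mobile:        {p.mean_D_mobile:.4g} ± {p.boot_sd_D:.2g} µm²/s (bootstrap)",
            f"bootstrap samples:    {p.n_boot}  seed: {p.seed}",
            "=" * 46,
        ]
        return "\n".join(lines)
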