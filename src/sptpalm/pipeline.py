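"""End-to-end orchestration: simulate/render → localize → link → filter →
motion analysis → spatial statistics → population summary.

A single ``RunConfig`` carries every stage parameter with the analysis
defaults (160 nm pixels, 0.1 s frames, 320 nm link gate, 4-12-frame
retention, 160 nm immobile box, α ∈ [0, 1.5], 480 nm pole depth, 1000
bootstrap samples).  One top-level seed fans out to per-stage seeds through
``numpy.random.SeedSequence`` so stages can be rerun independently yet
reproducibly; identical config and inputs give identical outputs.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as sio
from . import localize, motion, population, simulate, spatial, tracking
from .geometry import CellGeometry, build_cell
from .model import MobilityModel

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "stage_rng"]

logger = logging.getLogger(__name__)

_STAGES = ("simulate", "render", "localize", "bootstrap")


@dataclass(frozen=True)
class RunConfig:
    """All stage parameters of one analysis run."""

    # imaging
    pixel_size: float = 160.0  # nm
    frame_interval: float = 0.1  # s (10 Hz)
    detection_threshold: float = 5.0
    fit_window: int = 7
    # simulation
    cell_length: float = 5.0  # µm
    cell_width: float = 1.0  # µm
    n_particles: int = 2000
    frac_immobile: float = 0.131
    D_mobile: float = 0.0272  # µm²/s
    n_frames: int = 2500
    localization_sigma: float = 20.0  # nm
    activation_rate: float = 1.0
    mean_on_frames: float = 8.0
    hilo_depth: float = 300.0  # nm
    psf_sigma: float = 130.0  # nm
    photons: float = 1500.0
    background: float = 20.0
    # linking and retention
    max_link_distance: float = 320.0  # nm (two pixels)
    min_frames: int = 4
    max_frames: int = 12
    # motion analysis
    box_size: float = 160.0  # nm
    alpha_min: float = 0.0
    alpha_max: float = 1.5
    # spatial
    pole_depth: float = 480.0  # nm (three pixels)
    # population
    n_boot: int = 1000
    label: str = "condition"
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Deterministic per-stage generator derived from the run seed."""
    idx = _STAGES.index(stage)
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(idx,)))


@dataclass
class PipelineResult:
    config: RunConfig
    localizations: pd.DataFrame
    tracks: pd.DataFrame
    motion_results: pd.DataFrame
    summary: population.PopulationSummary
    regions: pd.DataFrame | None
    counts: dict
    ground_truth: list | None = None


def _simulation_config(cfg: RunConfig) -> simulate.SimulationConfig:
    return simulate.SimulationConfig(
        n_particles=cfg.n_particles,
        frac_immobile=cfg.frac_immobile,
        D_mobile=cfg.D_mobile,
        frame_interval=cfg.frame_interval,
        n_frames=cfg.n_frames,
        localization_sigma=cfg.localization_sigma,
        activation_rate=cfg.activation_rate,
        mean_on_frames=cfg.mean_on_frames,
        hilo_depth=cfg.hilo_depth,
    )


def default_cell(cfg: RunConfig) -> CellGeometry:
    """Cell placed so its footprint is positive in image coordinates."""
    margin = cfg.cell_width  # µm of clearance around the cell
    cx = cfg.cell_length / 2.0 + margin
    cy = cfg.cell_width / 2.0 + margin
    return build_cell(cfg.cell_length, cfg.cell_width, center=(cx, cy))


def movie_shape(cfg: RunConfig) -> tuple[int, int]:
    a = cfg.pixel_size / 1000.0
    w = int(np.ceil((cfg.cell_length + 2 * cfg.cell_width) / a))
    h = int(np.ceil((cfg.cell_width + 2 * cfg.cell_width) / a))
    return h, w


def run_pipeline(
    config: RunConfig,
    movie: np.ndarray | None = None,
    localizations: pd.DataFrame | None = None,
    tracks: pd.DataFrame | None = None,
    cell: spatial.CellRecord | None = None,
    output_dir: str | Path | None = None,
    render: bool = False,
) -> PipelineResult:
    """Run the remaining pipeline stages for whichever input is given.

    Entry points, most-upstream first: nothing (simulate a movie or track
    set from ``config``), a ``movie`` stack, a ``localizations`` table, or
    a pre-linked ``tracks`` table.  When ``output_dir`` is given, all
    intermediate CSVs plus a machine-readable manifest are written there.
    """
    counts: dict = {}
    truth = None
    geometry = None

    if tracks is None and localizations is None and movie is None:
        geometry = default_cell(config)
        sim_rng = stage_rng(config.seed, "simulate")
        truth, obs = simulate.simulate_tracks(geometry, _simulation_config(config), sim_rng)
        counts["ground_truth_particles"] = len(truth)
        if render:
            vis_rows = []
            for t in truth:
                if t.visible.any():
                    vis_rows.append(
                        pd.DataFrame(
                            {
                                "frame": t.frames[t.visible],
                                "x_nm": t.positions[t.visible, 0] * 1000.0,
                                "y_nm": t.positions[t.visible, 1] * 1000.0,
                            }
                        )
                    )
            emitters = (
                pd.concat(vis_rows, ignore_index=True)
                if vis_rows
                else pd.DataFrame(columns=["frame", "x_nm", "y_nm"])
            )
            movie = simulate.render_movie(
                emitters,
                n_frames=config.n_frames,
                shape=movie_shape(config),
                psf_sigma=config.psf_sigma,
                photons=config.photons,
                background=config.background,
                pixel_size=config.pixel_size,
                rng=stage_rng(config.seed, "render"),
            )
        else:
            localizations = obs.rename(columns={"particle_id": "cell_id"})[
                ["frame", "x_nm", "y_nm"]
            ]
            counts["observed_localizations"] = len(localizations)

    if localizations is None and tracks is None:
        assert movie is not None
        imaging = localize.ImagingConfig(
            pixel_size=config.pixel_size,
            frame_interval=config.frame_interval,
            detection_threshold=config.detection_threshold,
            fit_window=config.fit_window,
        )
        rejections = localize.RejectionLog()
        localizations = localize.localize_movie(movie, imaging, log=rejections)
        counts["localizations"] = len(localizations)
        counts["fit_rejections"] = rejections.total()

    if tracks is None:
        assert localizations is not None
        tracks = tracking.link_localizations(localizations, config.max_link_distance)
        counts["linked_tracks"] = int(tracks["track_id"].nunique()) if len(tracks) else 0

    model = MobilityModel(
        tracks,
        frame_interval=config.frame_interval,
        box_size=config.box_size,
        alpha_bounds=(config.alpha_min, config.alpha_max),
        min_frames=config.min_frames,
        max_frames=config.max_frames,
    )
    counts["retained_tracks"] = int(model.tracks["track_id"].nunique()) if len(model.tracks) else 0
    counts["rejected_too_short"] = model.n_too_short
    counts["rejected_too_long"] = model.n_too_long
    boot_seed = int(stage_rng(config.seed, "bootstrap").integers(2**31 - 1))
    results = model.fit(label=config.label, n_boot=config.n_boot, seed=boot_seed)
    counts["immobile"] = results.population.n_immobile
    counts["mobile_alpha_retained"] = results.population.n_mobile

    regions = None
    if cell is not None and len(model.tracks):
        regions = spatial.assign_regions(model.tracks, cell, config.pole_depth)
        frac, n_pole, n_non = spatial.polar_fraction(regions)
        counts["polar_tracks"] = n_pole
        counts["nonpolar_tracks"] = n_non

    result = PipelineResult(
        config=config,
        localizations=localizations if localizations is not None else pd.DataFrame(),
        tracks=model.tracks,
        motion_results=results.per_track,
        summary=results.population,
        regions=regions,
        counts=counts,
        ground_truth=truth,
    )

    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        if len(result.localizations) and set(sio.LOCALIZATION_SCHEMA) <= set(
            result.localizations.columns
        ):
            sio.write_table(out / "localizations.csv", result.localizations, sio.LOCALIZATION_SCHEMA)
        sio.write_table(out / "tracks.csv", result.tracks[sio.TRACK_SCHEMA] if len(result.tracks) else result.tracks)
        sio.write_table(out / "motion.csv", result.motion_results)
        sio.write_table(out / "summary.csv", _summary_frame(results.population))
        if regions is not None:
            sio.write_table(out / "regions.csv", regions)
        sio.write_manifest(out / "manifest.json", config.to_dict(), counts, config.seed)
    return result


def _summary_frame(s: population.PopulationSummary) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(s)])[sio.SUMMARY_SCHEMA]
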