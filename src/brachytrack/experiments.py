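"""Scripted evaluation campaigns and published reference-table recomputation.

Three campaigns mirror how the tracking system is characterized:

1. **Collimator sweep** — vary septal thickness and collimator height at a
   fixed 0.6 mm hole pitch and record FWHM / SNR / total counts of the
   on-axis point-response image (collimator optimization).
2. **Displacement scans** — step the source away from the isocenter along an
   axis (or the y-z diagonal) and record per-panel image metrics plus the
   end-to-end reconstruction error at each position.
3. **Patient scenario** — localize the 19 tandem-and-ovoid dwell positions
   of a clinical treatment plan.

The published reference tables (solid-phantom scans along x/y/z and the
19-dwell patient case, with original coordinates, reconstructed coordinates
and Euclidean distances) ship as CSV fixtures and every printed distance and
summary average is recomputed from the stored coordinate pairs by
:func:`recompute_reference_metrics`.
"""

from __future__ import annotations

import importlib.resources as resources
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, MetricError
from .geometry import (
    CollimatorSpec,
    DetectorSpec,
    Panel,
    SourceState,
    SystemLayout,
    build_layout,
    default_layout,
)
from .image_metrics import extract_profiles, fwhm, snr, total_counts
from .localize import ErrorSummary, TrackResult, centroid, position_error, summarize_errors
from .recon import (
    DivergingProjector,
    SIRTConfig,
    VolumeGrid,
    make_projector,
    prepare_projections,
    sirt_reconstruct,
)
from .transport import CountImage, TransportConfig, acquire_all, expected_image

__all__ = [
    "SweepGrid",
    "DisplacementScan",
    "ReferenceTables",
    "PipelineConfig",
    "PRINTED_SUMMARY",
    "DOCUMENTED_OUTLIER_CELLS",
    "DOCUMENTED_OUTLIER_SUMMARIES",
    "track_source",
    "run_collimator_sweep",
    "run_displacement_scan",
    "run_patient_scenario",
    "recompute_reference_metrics",
]


# ---------------------------------------------------------------------------
# reference tables
# ---------------------------------------------------------------------------

#: Printed summary statistics of the reference study.  Solid-phantom values
#: use the dedupe-on convention (the shared origin row of the three scan
#: tables counts once -> 25 unique positions).
PRINTED_SUMMARY: dict[str, float] = {
    "solid_mean_abs_error_x": 0.440,
    "solid_mean_abs_error_y": 0.423,
    "solid_mean_abs_error_z": 0.764,
    "solid_mean_distance": 1.146,
    "solid_mean_distance_excl_70_80": 0.889,
    "patient_mean_abs_error_x": 0.274,
    "patient_mean_abs_error_y": 0.178,
    "patient_mean_abs_error_z": 0.401,
    "patient_mean_distance": 0.586,
}

#: Distance cells whose printed value is inconsistent with their own printed
#: coordinate pair beyond one printed ulp (0.001): the published tables were
#: evidently summarized from unrounded coordinates.  The recomputed values
#: are frozen here and asserted instead of the misprints.
DOCUMENTED_OUTLIER_CELLS: dict[str, float] = {
    "z_40": 1.238,  # printed 1.245
    "Ovoid2_1": 0.480,  # printed 0.475
}

#: Printed summary averages with the same provenance problem.
DOCUMENTED_OUTLIER_SUMMARIES: dict[str, float] = {
    "solid_mean_abs_error_z": 0.768,  # printed 0.764
}

_SOLID_FILES = ("solid_phantom_x.csv", "solid_phantom_y.csv", "solid_phantom_z.csv")


def _load_csv(name: str) -> pd.DataFrame:
    with resources.files("brachytrack.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


@dataclass
class ReferenceTables:
    """The published solid-phantom and patient reference tables."""

    solid_x: pd.DataFrame
    solid_y: pd.DataFrame
    solid_z: pd.DataFrame
    patient: pd.DataFrame

    @classmethod
    def load(cls) -> "ReferenceTables":
        sx, sy, sz = (_load_csv(f) for f in _SOLID_FILES)
        return cls(sx, sy, sz, _load_csv("patient_dwell.csv"))

    def solid_frames(self) -> list[pd.DataFrame]:
        return [self.solid_x, self.solid_y, self.solid_z]

    @staticmethod
    def _to_results(frame: pd.DataFrame) -> list[TrackResult]:
        out = []
        for row in frame.itertuples(index=False):
            out.append(
                position_error(
                    (row.x_orig, row.y_orig, row.z_orig),
                    (row.x_rec, row.y_rec, row.z_rec),
                    label=row.label,
                )
            )
        return out

    def solid_results(self) -> list[TrackResult]:
        """Tracking results recomputed from the three solid-phantom tables."""
        out: list[TrackResult] = []
        for frame in self.solid_frames():
            out.extend(self._to_results(frame))
        return out

    def patient_results(self) -> list[TrackResult]:
        return self._to_results(self.patient)

    def patient_positions(self) -> list[tuple[str, np.ndarray]]:
        """Labelled original dwell coordinates of the patient plan."""
        return [
            (row.label, np.array([row.x_orig, row.y_orig, row.z_orig]))
            for row in self.patient.itertuples(index=False)
        ]


def recompute_reference_metrics(
    tables: ReferenceTables | None = None, tol: float = 1e-3
) -> dict:
    """Recompute every printed distance cell and summary average from the
    stored coordinate pairs and compare with the printed values.

    A cell or summary *matches* when |recomputed - printed| <= ``tol`` (one
    printed ulp).  Documented printed-rounding outliers — cells whose printed
    value cannot be reproduced from the printed coordinates — are instead
    checked against their frozen recomputed values, and any *undocumented*
    mismatch marks the report as failed.
    """
    tables = tables or ReferenceTables.load()
    cells = []
    undocumented = 0
    for frame, table_name in zip(
        tables.solid_frames() + [tables.patient],
        ["solid_x", "solid_y", "solid_z", "patient"],
    ):
        for res, printed in zip(tables._to_results(frame), frame["distance_printed"]):
            rec = float(np.round(res.euclidean_distance, 3))
            match = abs(res.euclidean_distance - printed) <= tol + 1e-12
            documented = res.label in DOCUMENTED_OUTLIER_CELLS
            if documented:
                match_frozen = bool(abs(rec - DOCUMENTED_OUTLIER_CELLS[res.label]) <= 1e-9)
            else:
                match_frozen = None
            if not match and not documented:
                undocumented += 1
            cells.append(
                {
                    "table": table_name,
                    "label": res.label,
                    "recomputed": rec,
                    "printed": float(printed),
                    "match": bool(match),
                    "documented_outlier": documented,
                    "matches_frozen_recomputation": match_frozen,
                }
            )

    solid = tables.solid_results()
    patient = tables.patient_results()
    s_all = summarize_errors(solid, dedupe=True)
    s_near = summarize_errors(
        solid, dedupe=True, keep=lambda r: float(np.abs(r.original).max()) < 65.0
    )
    s_pat = summarize_errors(patient, dedupe=False)
    recomputed = {
        "solid_mean_abs_error_x": s_all.mean_abs_error[0],
        "solid_mean_abs_error_y": s_all.mean_abs_error[1],
        "solid_mean_abs_error_z": s_all.mean_abs_error[2],
        "solid_mean_distance": s_all.mean_distance,
        "solid_mean_distance_excl_70_80": s_near.mean_distance,
        "patient_mean_abs_error_x": s_pat.mean_abs_error[0],
        "patient_mean_abs_error_y": s_pat.mean_abs_error[1],
        "patient_mean_abs_error_z": s_pat.mean_abs_error[2],
        "patient_mean_distance": s_pat.mean_distance,
    }
    summaries = {}
    for name, printed in PRINTED_SUMMARY.items():
        value = float(recomputed[name])
        match = abs(value - printed) <= tol + 1e-12
        documented = name in DOCUMENTED_OUTLIER_SUMMARIES
        if documented:
            frozen_ok = bool(
                abs(np.round(value, 3) - DOCUMENTED_OUTLIER_SUMMARIES[name]) <= 1e-9
            )
        else:
            frozen_ok = None
        if not match and not documented:
            undocumented += 1
        summaries[name] = {
            "recomputed": value,
            "recomputed_rounded": float(np.round(value, 3)),
            "printed": printed,
            "match": bool(match),
            "documented_outlier": documented,
            "matches_frozen_recomputation": frozen_ok,
        }
    doc_ok = all(
        c["matches_frozen_recomputation"] is not False for c in cells
    ) and all(s["matches_frozen_recomputation"] is not False for s in summaries.values())
    return {
        "n_unique_solid_positions": s_all.n,
        "cells": cells,
        "summaries": summaries,
        "n_undocumented_mismatches": undocumented,
        "all_pass": undocumented == 0 and doc_ok,
    }


# ---------------------------------------------------------------------------
# campaign configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SweepGrid:
    """Collimator parameter grid at fixed 0.6 mm hole pitch."""

    heights: tuple[float, ...] = (20.0, 25.0, 30.0, 35.0, 40.0, 45.0, 50.0)
    septal_thicknesses: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4)
    pitch: float = 0.6

    def __post_init__(self) -> None:
        for t in self.septal_thicknesses:
            if not 0 < t < self.pitch:
                raise ConfigurationError(
                    f"septal thickness {t} leaves no open hole at pitch {self.pitch}"
                )

    def collimators(self):
        for t in self.septal_thicknesses:
            for h in self.heights:
                yield CollimatorSpec(
                    hole_size_d=self.pitch - t, septal_thickness_t=t, height_h=h
                )


@dataclass(frozen=True)
class DisplacementScan:
    """Stepwise source displacement from the isocenter."""

    axis: str = "y"
    step: float = 10.0
    max: float = 80.0

    _DIRECTIONS = {
        "x": np.array([1.0, 0.0, 0.0]),
        "y": np.array([0.0, 1.0, 0.0]),
        "z": np.array([0.0, 0.0, 1.0]),
        "diagonal-yz": np.array([0.0, 1.0, 1.0]) / np.sqrt(2.0),
    }

    def __post_init__(self) -> None:
        if self.axis not in self._DIRECTIONS:
            raise ConfigurationError(f"unknown scan axis {self.axis!r}")
        if self.step <= 0:
            raise ConfigurationError("step must be > 0")
        if abs(self.max / self.step - round(self.max / self.step)) > 1e-9:
            raise ConfigurationError("max must be a multiple of step")

    def positions(self) -> list[np.ndarray]:
        """Source centers including the origin."""
        direction = self._DIRECTIONS[self.axis]
        n = int(round(self.max / self.step))
        return [k * self.step * direction for k in range(n + 1)]


@dataclass
class PipelineConfig:
    """End-to-end settings: acquisition -> up-sampling -> SIRT -> centroid.

    ``noiseless`` swaps the Monte Carlo acquisition for the analytic expected
    image (useful for accuracy studies free of counting noise).
    """

    layout: SystemLayout = field(default_factory=default_layout)
    transport: TransportConfig = field(default_factory=TransportConfig)
    grid: VolumeGrid = field(default_factory=VolumeGrid.centered)
    upsample_factor: int = 4
    gaussian_sigma: float = 0.6
    sirt: SIRTConfig = field(default_factory=SIRTConfig)
    threshold_fraction: float = 0.3
    refine_passes: int = 1
    noiseless: bool = False

    def projector(self) -> DivergingProjector:
        return make_projector(
            self.layout, self.grid, self.upsample_factor, self.gaussian_sigma
        )


# ---------------------------------------------------------------------------
# campaigns
# ---------------------------------------------------------------------------


def _acquire(cfg: PipelineConfig, source: SourceState) -> list:
    if cfg.noiseless:
        return [
            expected_image(panel, source, cfg.transport) for panel in cfg.layout
        ]
    return acquire_all(cfg.layout, source, cfg.transport)


def track_source(
    cfg: PipelineConfig,
    source: SourceState,
    projector: DivergingProjector | None = None,
    label: str = "",
) -> tuple[TrackResult, list]:
    """Localize one source position through the full pipeline.

    Acquisition -> Gaussian up-sampling -> SIRT -> thresholded centroid,
    followed by ``cfg.refine_passes`` fixed-point bias-correction passes:
    the known deterministic localization systematic (the hole-lattice
    quantization of the collimator response) is predicted by running the
    package's own noiseless forward model at the current estimate and
    subtracted.  Returns the tracking result and the acquired images.
    """
    images = _acquire(cfg, source)
    projector = projector or cfg.projector()

    def _localize(imgs) -> np.ndarray:
        stack = prepare_projections(
            imgs, cfg.layout, cfg.upsample_factor, cfg.gaussian_sigma
        )
        volume = sirt_reconstruct(projector, stack, cfg.sirt)
        return centroid(volume, cfg.threshold_fraction)

    estimate = _localize(images)
    reconstructed = estimate.copy()
    for _ in range(cfg.refine_passes):
        try:
            sim = [
                expected_image(panel, source.at(reconstructed), cfg.transport)
                for panel in cfg.layout
            ]
            predicted = _localize(sim)
        except MetricError:  # estimate wandered outside the imaged volume
            break
        reconstructed = reconstructed + (estimate - predicted)
    return position_error(source.center, reconstructed, label=label), images


def _image_quality(image, pitch: float) -> dict:
    row = {"total_counts": total_counts(image)}
    try:
        vert, horiz = extract_profiles(image, pitch)
    except MetricError:  # no signal at all (source outside this panel's reach)
        row.update({f"{m}_{d}": np.nan for m in ("fwhm", "snr")
                    for d in ("vertical", "horizontal")})
        return row
    for direction, prof in [("vertical", vert), ("horizontal", horiz)]:
        try:
            row[f"fwhm_{direction}"] = fwhm(prof)
        except MetricError:
            row[f"fwhm_{direction}"] = np.nan
        try:
            row[f"snr_{direction}"] = snr(prof)
        except MetricError:
            row[f"snr_{direction}"] = np.nan
    return row


def run_collimator_sweep(
    grid: SweepGrid | None = None,
    source: SourceState | None = None,
    transport: TransportConfig | None = None,
    detector: DetectorSpec | None = None,
    distance: float = 500.0,
    monte_carlo: bool = True,
) -> pd.DataFrame:
    """FWHM / SNR / total counts of a single panel versus collimator geometry.

    One panel at ring angle 0 views an on-axis source ``distance`` mm from
    the collimator entrance face.  Rows: one per (height, septal thickness,
    profile direction).
    """
    grid = grid or SweepGrid()
    source = source or SourceState(exposure_time=5.0)
    transport = transport or TransportConfig(ambient_background=2.0)
    detector = detector or DetectorSpec()
    rows = []
    for col in grid.collimators():
        layout = build_layout(distance, [0.0], [0.0], detector, col)
        panel = layout[0]
        if monte_carlo:
            img = acquire_all(layout, source, transport)[0]
        else:
            img = expected_image(panel, source, transport)
        quality = _image_quality(img, detector.pixel_pitch)
        for direction in ("vertical", "horizontal"):
            rows.append(
                {
                    "h": col.height_h,
                    "t": col.septal_thickness_t,
                    "d": col.hole_size_d,
                    "direction": direction,
                    "fwhm_mm": quality[f"fwhm_{direction}"],
                    "snr": quality[f"snr_{direction}"],
                    "total_counts": quality["total_counts"],
                }
            )
    return pd.DataFrame(rows)


def run_displacement_scan(
    scan: DisplacementScan,
    cfg: PipelineConfig | None = None,
    source: SourceState | None = None,
) -> pd.DataFrame:
    """Full-pipeline accuracy and per-panel image quality along a scan.

    Returns one row per (position, panel) with the panel's FWHM/SNR plus the
    position's reconstruction error (repeated across its panel rows).
    """
    cfg = cfg or PipelineConfig()
    base = source or SourceState()
    projector = cfg.projector()
    pitch = cfg.layout[0].detector.pixel_pitch
    rows = []
    for pos in scan.positions():
        src = base.at(pos)
        disp = float(np.linalg.norm(pos))
        label = f"{scan.axis}_{disp:g}"
        result, images = track_source(cfg, src, projector=projector, label=label)
        for panel, img in zip(cfg.layout, images):
            row = {
                "label": label,
                "axis": scan.axis,
                "displacement_mm": disp,
                "panel_id": panel.panel_id,
                **_image_quality(img, pitch),
                "x_orig": src.center[0],
                "y_orig": src.center[1],
                "z_orig": src.center[2],
                "x_rec": result.reconstructed[0],
                "y_rec": result.reconstructed[1],
                "z_rec": result.reconstructed[2],
                "euclidean_distance": result.euclidean_distance,
            }
            rows.append(row)
    return pd.DataFrame(rows)


def run_patient_scenario(
    cfg: PipelineConfig | None = None,
    tables: ReferenceTables | None = None,
    source: SourceState | None = None,
) -> list[TrackResult]:
    """Track the 19 patient dwell positions (tandem + two ovoids)."""
    cfg = cfg or PipelineConfig()
    tables = tables or ReferenceTables.load()
    base = source or SourceState()
    projector = cfg.projector()
    results = []
    for label, pos in tables.patient_positions():
        result, _ = track_source(cfg, base.at(pos), projector=projector, label=label)
        results.append(result)
    return results
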