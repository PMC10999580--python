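"""YAML run-configuration loading and validation.

A run configuration describes the full system — detector, collimator, panel
ring, source, transport, reconstruction and localization settings — with
explicit units (mm, degrees, seconds, mCi).  The bundled default
configuration reproduces the reference system: a 38 x 38 diverging
collimator with d = t = 0.3 mm, h = 30 mm and 45-degree acceptance on six
panels at 500 mm radius, 36 degrees apart from 270 to 90 degrees.
"""

from __future__ import annotations

import importlib.resources as resources
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from .errors import ConfigurationError
from .experiments import PipelineConfig
from .geometry import (
    MCI_TO_BQ,
    CollimatorSpec,
    DetectorSpec,
    SourceState,
    SystemLayout,
    build_layout,
)
from .recon import SIRTConfig, VolumeGrid
from .transport import TransportConfig

__all__ = ["load_config", "default_config", "pipeline_from_config", "source_from_config"]

_SCHEMA: dict[str, dict[str, type | tuple[type, ...]]] = {
    "layout": {
        "radius": (int, float),
        "ring_angles": list,
        "z_offsets": list,
    },
    "detector": {
        "pixels_per_side": int,
        "pixel_pitch": (int, float),
        "active_pixel_size": (int, float),
        "scintillator_thickness": (int, float),
        "face_size": (int, float),
    },
    "collimator": {
        "hole_size_d": (int, float),
        "septal_thickness_t": (int, float),
        "height_h": (int, float),
        "holes_per_side": int,
        "acceptance_angle": (int, float),
        "attenuation_coeff": (int, float),
        "focal_length_override": (int, float, type(None)),
    },
    "source": {
        "center": list,
        "axis": list,
        "diameter": (int, float),
        "length": (int, float),
        "activity_mci": (int, float),
        "exposure_time": (int, float),
    },
    "transport": {
        "n_photons": int,
        "detection_efficiency": (int, float),
        "septal_penetration": bool,
        "attenuation_coeff": (int, float, type(None)),
        "rng_seed": int,
        "emitted_photons": (int, float, type(None)),
        "source_subsamples": int,
        "ambient_background": (int, float),
        "septal_samples": int,
    },
    "recon": {
        "upsample_factor": int,
        "gaussian_sigma": (int, float),
        "volume_extent": (int, float),
        "voxel_size": (int, float),
        "iterations": int,
        "nonnegativity": bool,
    },
    "localize": {
        "threshold_fraction": (int, float),
        "refine_passes": int,
    },
    "noiseless": {},  # top-level boolean handled separately
}


def _validate(cfg: Mapping[str, Any]) -> None:
    if not isinstance(cfg, Mapping):
        raise ConfigurationError("configuration root must be a mapping")
    for section, content in cfg.items():
        if section == "noiseless":
            if not isinstance(content, bool):
                raise ConfigurationError("'noiseless' must be a boolean")
            continue
        if section not in _SCHEMA:
            raise ConfigurationError(f"unknown configuration section {section!r}")
        if not isinstance(content, Mapping):
            raise ConfigurationError(f"section {section!r} must be a mapping")
        allowed = _SCHEMA[section]
        for key, value in content.items():
            if key not in allowed:
                raise ConfigurationError(f"unknown key {section}.{key}")
            expected = allowed[key]
            if not isinstance(value, expected):
                raise ConfigurationError(
                    f"{section}.{key} must be of type {expected}, got {type(value).__name__}"
                )


def load_config(path: str | Path | None = None) -> dict:
    """Load and validate a YAML config; ``None`` loads the bundled default."""
    if path is None:
        text = resources.files("brachytrack.data").joinpath("default_config.yaml").read_text()
    else:
        p = Path(path)
        if not p.exists():
            raise ConfigurationError(f"configuration file not found: {p}")
        text = p.read_text()
    try:
        cfg = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"invalid YAML: {exc}") from exc
    _validate(cfg or {})
    return cfg or {}


def default_config() -> dict:
    return load_config(None)


def _merged(cfg: Mapping, section: str) -> dict:
    base = default_config().get(section, {})
    out = dict(base)
    out.update(cfg.get(section, {}))
    return out


def layout_from_config(cfg: Mapping) -> SystemLayout:
    det = DetectorSpec(**_merged(cfg, "detector"))
    col = CollimatorSpec(**_merged(cfg, "collimator"))
    lay = _merged(cfg, "layout")
    return build_layout(lay["radius"], lay["ring_angles"], lay["z_offsets"], det, col)


def source_from_config(cfg: Mapping) -> SourceState:
    s = _merged(cfg, "source")
    return SourceState(
        center=np.asarray(s["center"], dtype=float),
        axis=np.asarray(s.get("axis", [0, 0, 1]), dtype=float),
        diameter=s["diameter"],
        length=s["length"],
        activity_bq=s["activity_mci"] * MCI_TO_BQ,
        exposure_time=s["exposure_time"],
    )


def pipeline_from_config(cfg: Mapping, seed: int | None = None) -> PipelineConfig:
    """Assemble the end-to-end pipeline settings from a validated config."""
    transport_kwargs = _merged(cfg, "transport")
    if seed is not None:
        transport_kwargs["rng_seed"] = int(seed)
    rec = _merged(cfg, "recon")
    loc = _merged(cfg, "localize")
    return PipelineConfig(
        layout=layout_from_config(cfg),
        transport=TransportConfig(**transport_kwargs),
        grid=VolumeGrid.centered(rec["volume_extent"], rec["voxel_size"]),
        upsample_factor=rec["upsample_factor"],
        gaussian_sigma=rec["gaussian_sigma"],
        sirt=SIRTConfig(iterations=rec["iterations"], nonnegativity=rec["nonnegativity"]),
        threshold_fraction=loc["threshold_fraction"],
        refine_passes=loc.get("refine_passes", 1),
        noiseless=bool(cfg.get("noiseless", False)),
    )
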