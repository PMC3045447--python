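"""Pipeline configuration: one nested mapping, YAML on disk.

``default_config()`` is the package's default study setup: the 256³ / 4 µm
phantom with 21 alveoli on the 100–150 µm immature-mouse diameter range,
imaged at 18 keV over 1.2 m onto 13 µm detector pixels with 240 projections
(a desk-scale count; the emulated experiment used 1296), reconstructed with
the ramp filter.  Any subset of keys may be overridden from a config file;
unknown keys are rejected to catch typos.
"""

from __future__ import annotations

import copy
from typing import Any, Dict, Optional

from .forward_model import BeamGeometry
from .phantom import (
    AirwayTreeParams, AlveolarParams, LungPhantomSpec, RibParams,
)

__all__ = ["default_config", "merge_config", "phantom_spec_from_config",
           "beam_geometry_from_config"]


def default_config() -> Dict[str, Any]:
    return {
        "seed": 0,
        "phantom": {
            "extent_um": [1024.0, 1024.0, 1024.0],
            "pitch_um": 4.0,
            "body_radius_um": 480.0,
            "tree": {
                "depth": 5,
                "root_radius_um": 50.0,
                "radius_ratio": 0.85,
                "branch_angle_deg": [30.0, 55.0],
                "root_length_um": 200.0,
                "length_ratio": 0.82,
                "root_start_um": [90.0, 512.0, 512.0],
            },
            "alveoli": {
                "count": 21,
                "d_range_um": [100.0, 150.0],
                "gap_um": 26.0,
                "jitter_deg": 100.0,
                "max_tries_per_alveolus": 800,
            },
            "ribs": {
                "count": 3,
                "tube_radius_um": 60.0,
                "arc_radius_um": 410.0,
                "arc_span_deg": 110.0,
            },
        },
        "beam": {
            "energy_keV": 18.0,
            "z_m": 1.2,
            "detector_pitch_um": 13.0,
            "n_angles": 240,
            "photons_per_pixel": 1.0e4,
        },
        "reconstruction": {"filter": "ramp"},
        "segmentation": {
            "airway_threshold": None,   # None -> automatic valley threshold
            "bone_threshold": None,     # None -> automatic (see pipeline)
            "connectivity": 26,
            "seed_voxel": None,         # None -> trachea lumen, mapped
        },
        "morphometry": {
            # components below this volume are unresolved debris, not alveoli
            "min_component_volume_um3": 1.5e5,
            # alveoli are near-spheroidal; drop elongated fragments
            "max_aspect_ratio": 2.5,
        },
        "propagator": "exact",
    }


def merge_config(overrides: Optional[Dict[str, Any]]) -> Dict[str, Any]:
    """Deep-merge user overrides onto the defaults; unknown keys raise."""
    cfg = default_config()
    if overrides:
        _merge(cfg, overrides, path="")
    return cfg


def _merge(base: Dict[str, Any], over: Dict[str, Any], path: str) -> None:
    for key, value in over.items():
        if key not in base:
            raise KeyError(f"unknown config key {path + key!r}")
        if isinstance(base[key], dict) and isinstance(value, dict):
            _merge(base[key], value, path + key + ".")
        else:
            base[key] = copy.deepcopy(value)


def phantom_spec_from_config(cfg: Dict[str, Any],
                             seed: Optional[int] = None) -> LungPhantomSpec:
    p = cfg["phantom"]
    return LungPhantomSpec(
        extent_um=tuple(p["extent_um"]),
        pitch_um=float(p["pitch_um"]),
        body_radius_um=float(p["body_radius_um"]),
        tree=AirwayTreeParams(
            depth=int(p["tree"]["depth"]),
            root_radius_um=float(p["tree"]["root_radius_um"]),
            radius_ratio=float(p["tree"]["radius_ratio"]),
            branch_angle_deg=tuple(p["tree"]["branch_angle_deg"]),
            root_length_um=float(p["tree"]["root_length_um"]),
            length_ratio=float(p["tree"]["length_ratio"]),
            root_start_um=tuple(p["tree"]["root_start_um"]),
        ),
        alveoli=AlveolarParams(
            count=int(p["alveoli"]["count"]),
            d_range_um=tuple(p["alveoli"]["d_range_um"]),
            gap_um=float(p["alveoli"]["gap_um"]),
            jitter_deg=float(p["alveoli"]["jitter_deg"]),
            max_tries_per_alveolus=int(p["alveoli"]["max_tries_per_alveolus"]),
        ),
        ribs=RibParams(
            count=int(p["ribs"]["count"]),
            tube_radius_um=float(p["ribs"]["tube_radius_um"]),
            arc_radius_um=float(p["ribs"]["arc_radius_um"]),
            arc_span_deg=float(p["ribs"]["arc_span_deg"]),
        ),
        seed=int(cfg["seed"] if seed is None else seed),
    )


def beam_geometry_from_config(cfg: Dict[str, Any]) -> BeamGeometry:
    b = cfg["beam"]
    return BeamGeometry(
        energy_keV=float(b["energy_keV"]),
        z_m=float(b["z_m"]),
        detector_pitch_um=float(b["detector_pitch_um"]),
        n_angles=int(b["n_angles"]),
        photons_per_pixel=float(b["photons_per_pixel"]),
    )
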