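"""Volume, table, config and manifest I/O.

Volumes travel as multi-page TIFF stacks (one page per z slice, 32-bit
float for gray volumes, uint32 for label volumes) with a JSON metadata
sidecar (``<stem>.meta.json``) holding the voxel pitch and provenance;
label volumes additionally carry their legend in the sidecar.  Morphometry
tables are CSV; run manifests and configs are JSON/YAML.  All round-trips
are lossless for these dtypes.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Dict, Optional, Tuple

import numpy as np
import pandas as pd
import tifffile
import yaml

from .reconstruction import CTVolume
from .segmentation import LabelVolume

__all__ = [
    "write_volume", "read_volume",
    "write_ct", "read_ct",
    "write_labels", "read_labels",
    "write_stats", "read_stats",
    "write_manifest", "read_manifest",
    "load_config", "save_config",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def write_volume(
    path: str | Path,
    array: np.ndarray,
    pitch_um: float,
    meta: Optional[Dict[str, Any]] = None,
) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, array, photometric="minisblack")
    payload = {"pitch_um": float(pitch_um), "dtype": str(array.dtype),
               "shape": list(array.shape)}
    if meta:
        payload["meta"] = _jsonable(meta)
    _sidecar(path).write_text(json.dumps(payload, indent=2))
    return path


def read_volume(path: str | Path) -> Tuple[np.ndarray, Dict[str, Any]]:
    path = Path(path)
    try:
        array = tifffile.imread(path)
    except Exception as exc:
        raise IOError(f"cannot read TIFF volume {path}: {exc}") from exc
    sidecar = _sidecar(path)
    info: Dict[str, Any] = {}
    if sidecar.exists():
        info = json.loads(sidecar.read_text())
        if "shape" in info and list(array.shape) != info["shape"]:
            raise IOError(
                f"TIFF {path} shape {list(array.shape)} disagrees with its "
                f"sidecar {info['shape']} (truncated file?)"
            )
    return array, info


def write_ct(path: str | Path, ct: CTVolume) -> Path:
    return write_volume(path, ct.values.astype(np.float32), ct.pitch_um, ct.meta)


def read_ct(path: str | Path) -> CTVolume:
    array, info = read_volume(path)
    return CTVolume(values=array.astype(np.float32),
                    pitch_um=float(info.get("pitch_um", 1.0)),
                    meta=info.get("meta", {}))


def write_labels(path: str | Path, labels: LabelVolume) -> Path:
    meta = dict(labels.meta)
    meta["legend"] = {str(k): v for k, v in labels.legend.items()}
    return write_volume(path, labels.labels.astype(np.uint32),
                        labels.pitch_um, meta)


def read_labels(path: str | Path) -> LabelVolume:
    array, info = read_volume(path)
    meta = info.get("meta", {})
    legend = {int(k): v for k, v in meta.pop("legend", {}).items()}
    return LabelVolume(labels=array.astype(np.uint32), legend=legend,
                       pitch_um=float(info.get("pitch_um", 1.0)), meta=meta)


def write_stats(path: str | Path, stats: pd.DataFrame) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    stats.to_csv(path, index=False)
    return path


def read_stats(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_manifest(path: str | Path, manifest: Dict[str, Any]) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(_jsonable(manifest), indent=2, sort_keys=True))
    return path


def read_manifest(path: str | Path) -> Dict[str, Any]:
    return json.loads(Path(path).read_text())


def load_config(path: str | Path) -> Dict[str, Any]:
    """Read a nested key/value pipeline config (YAML)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def save_config(path: str | Path, config: Dict[str, Any]) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(_jsonable(config), fh, sort_keys=False)
    return path


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, Path):
        return str(obj)
    return obj
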