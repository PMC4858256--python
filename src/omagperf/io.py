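"""Readers/writers for the interchange formats and the run configuration.

Volumes travel as multi-page TIFF plus a JSON sidecar header.  Page order
is location-major, repeat-minor, with two pages per B-scan (amplitude then
phase) so the complex signal survives format conversion.  Flow volumes and
en-face maps are float32 TIFF; layer models are JSON with the surface
arrays inline; tables are CSV.  The run configuration is a YAML-round-trip
dataclass whose defaults are the pipeline's canonical parameter values.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .flow import FlowVolume, RepeatedBScanVolume
from .segmentation import LayerModel

__all__ = [
    "RunConfig",
    "write_volume",
    "read_volume",
    "write_flow",
    "read_flow",
    "write_enface",
    "read_enface",
    "write_layers",
    "read_layers",
    "write_ground_truth",
]

VOLUME_TIFF = "volume.tiff"
VOLUME_SIDECAR = "volume.json"


@dataclass
class RunConfig:
    """All tunables of the simulate→stats pipeline with their defaults.

    Every default here is the canonical value used throughout the package:
    the 0-255 scaling mode, Frangi scales/beta, the 0.15 vesselness
    threshold, the signal-strength QC cutoff of 6, and the pooled t-test.
    """

    # scene / simulation
    nx: int = 128
    ny: int = 128
    nz: int = 192
    repeats: int = 4
    extent_mm: tuple[float, float] = (2.4, 2.4)
    disc_radius_mm: float = 0.75
    target_vessel_fraction: float = 0.5
    vessel_delta: float = 1.0
    noise_sd: float = 0.02
    # flow scaling
    scale_mode: str = "percentile"
    scale_percentile: float = 99.5
    # segmentation
    smooth_sigma: float = 2.0
    threshold_nsd: float = 2.0
    # vessel detection
    scales: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0)
    beta: float = 0.5
    vessel_threshold: float = 0.15
    vessel_low_threshold: float = 0.05
    threshold_method: str = "fixed"
    # QC & statistics
    qc_signal_cutoff: float = 6.0
    ttest_mode: str = "pooled"
    group_sizes: dict = field(default_factory=lambda: {"normal": 30, "POAG": 30, "NTG": 30})
    # bookkeeping
    seed: int = 0
    verbosity: int = 1

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["extent_mm"] = list(self.extent_mm)
        d["scales"] = list(self.scales)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "extent_mm" in d:
            d["extent_mm"] = tuple(d["extent_mm"])
        if "scales" in d:
            d["scales"] = tuple(d["scales"])
        return cls(**d)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def write_volume(vol: RepeatedBScanVolume, out_dir) -> Path:
    """Write a repeated-B-scan volume as multi-page TIFF + JSON sidecar.

    Pages are ordered location-major, repeat-minor, two pages per B-scan:
    amplitude first, then phase (radians), each an (nz, nx) float32 image.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    c = vol.data  # (ny, R, nx, nz)
    with tifffile.TiffWriter(out / VOLUME_TIFF) as tw:
        for y in range(vol.ny):
            for r in range(vol.repeats):
                b = c[y, r].T  # (nz, nx)
                tw.write(np.abs(b).astype(np.float32), contiguous=False)
                tw.write(np.angle(b).astype(np.float32), contiguous=False)
    sidecar = {
        "dims": {"nx": vol.nx, "ny": vol.ny, "nz": vol.nz},
        "repeats": vol.repeats,
        "extent_mm": list(vol.extent_mm),
        "ascan_rate_hz": vol.ascan_rate_hz,
        "seed": vol.seed,
        "page_order": "location-major, repeat-minor; amplitude page then phase page",
    }
    (out / VOLUME_SIDECAR).write_text(json.dumps(sidecar, indent=2, default=_json_default))
    return out


def read_volume(in_dir) -> RepeatedBScanVolume:
    src = Path(in_dir)
    sidecar_path = src / VOLUME_SIDECAR
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing volume sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    try:
        nx, ny, nz = (meta["dims"][k] for k in ("nx", "ny", "nz"))
        R = meta["repeats"]
    except KeyError as e:
        raise ValueError(f"corrupt volume header: missing {e}") from e
    with tifffile.TiffFile(src / VOLUME_TIFF) as tf:
        pages = np.stack([p.asarray() for p in tf.pages])
    expected = ny * R * 2
    if pages.shape[0] != expected or pages.shape[1:] != (nz, nx):
        raise ValueError(
            f"volume TIFF has {pages.shape} pages, header implies {expected}x({nz},{nx})"
        )
    amp = pages[0::2].reshape(ny, R, nz, nx)
    phase = pages[1::2].reshape(ny, R, nz, nx)
    data = (amp * np.exp(1j * phase)).transpose(0, 1, 3, 2)  # (ny, R, nx, nz)
    return RepeatedBScanVolume(
        data=data,
        extent_mm=tuple(meta.get("extent_mm", (2.4, 2.4))),
        ascan_rate_hz=meta.get("ascan_rate_hz", 68_000.0),
        seed=meta.get("seed"),
    )


def write_flow(flow: FlowVolume, path) -> Path:
    """Flow volume as multi-page float32 TIFF, one (nz, nx) page per y."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pages = np.moveaxis(flow.data, 1, 0).transpose(0, 2, 1)  # (ny, nz, nx)
    tifffile.imwrite(path, pages.astype(np.float32))
    sidecar = {
        "scaled": flow.scaled,
        "scale_factor": flow.scale_factor,
        "scale_mode": flow.scale_mode,
        "extent_mm": list(flow.extent_mm),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, default=_json_default))
    return path


def read_flow(path) -> FlowVolume:
    path = Path(path)
    pages = tifffile.imread(path)  # (ny, nz, nx)
    data = np.ascontiguousarray(pages.transpose(2, 0, 1)).astype(float)  # (nx, ny, nz)
    meta = {}
    if path.with_suffix(".json").exists():
        meta = json.loads(path.with_suffix(".json").read_text())
    return FlowVolume(
        data=data,
        scaled=meta.get("scaled", False),
        scale_factor=meta.get("scale_factor"),
        scale_mode=meta.get("scale_mode"),
        extent_mm=tuple(meta.get("extent_mm", (2.4, 2.4))),
    )


def write_enface(image: np.ndarray, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(image, dtype=np.float32))
    return path


def read_enface(path) -> np.ndarray:
    return np.asarray(tifffile.imread(path), dtype=float)


def write_layers(layers: LayerModel, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    doc = {
        "z_ilm": layers.z_ilm,
        "z_alc": layers.z_alc,
        "disc_mask": layers.disc_mask.astype(int) if layers.disc_mask is not None else None,
        "extent_mm": list(layers.extent_mm),
        "meta": {k: v for k, v in layers.meta.items() if not isinstance(v, np.ndarray)},
    }
    path.write_text(json.dumps(doc, default=_json_default))
    return path


def read_layers(path) -> LayerModel:
    doc = json.loads(Path(path).read_text())
    return LayerModel(
        z_ilm=np.asarray(doc["z_ilm"], dtype=float),
        z_alc=np.asarray(doc["z_alc"], dtype=float),
        disc_mask=(np.asarray(doc["disc_mask"], dtype=bool)
                   if doc.get("disc_mask") is not None else None),
        extent_mm=tuple(doc.get("extent_mm", (2.4, 2.4))),
        meta=doc.get("meta", {}),
    )


def write_ground_truth(gt, out_dir) -> Path:
    """Ground truth as compressed arrays + a small JSON summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(
        out / "ground_truth.npz",
        vessel_mask=gt.vessel_mask,
        decorrelation=gt.decorrelation,
        z_ilm=gt.z_ilm,
        z_alc=gt.z_alc,
        disc_mask=gt.disc_mask,
        enface_vessel_mask=gt.enface_vessel_mask,
    )
    (out / "ground_truth.json").write_text(json.dumps(
        {"vessel_fraction": gt.vessel_fraction,
         "disc_area_px": int(gt.disc_mask.sum())}, indent=2))
    return out
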