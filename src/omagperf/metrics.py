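"""Perfusion metrics within the disc margin, and scan-level QC.

Three dimensionless metrics on the en-face MIP image F (0-255 range),
restricted to the disc mask:

* flux              — mean of F/255 over all disc pixels;
* vessel area density — |vessel ∩ disc| / |disc|;
* normalized flux   — mean of F/255 over vessel pixels only, so the flux
  is evaluated inside the vessels irrespective of how much viable tissue
  remains.

The three are linked by the exact identity
``flux = d * nf + (1 - d) * b`` where ``d`` is the density, ``nf`` the
normalized flux and ``b`` the mean normalized flow over non-vessel disc
pixels — conservation of the disc sum, used as a cross-check.

Scan-level QC excludes eyes whose device signal strength (0-10) is below
the recommended cutoff of 6 or that show noticeable eye movement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .flow import DYNAMIC_RANGE

__all__ = [
    "PerfusionMetrics",
    "compute_flux",
    "compute_vessel_area_density",
    "compute_normalized_flux",
    "compute_perfusion_metrics",
    "qc_filter",
]

QC_SIGNAL_CUTOFF = 6


@dataclass
class PerfusionMetrics:
    flux: float
    vessel_area_density: float
    normalized_flux: float          # NaN when no vessel pixels (flagged)
    area_onh_px: int
    vessel_area_px: int
    normalized_flux_defined: bool = True
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("flux", "vessel_area_density"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.normalized_flux_defined and not 0.0 <= self.normalized_flux <= 1.0:
            raise ValueError("normalized flux outside [0, 1]")
        if self.vessel_area_px > self.area_onh_px:
            raise ValueError("vessel area exceeds disc area")


def _check_enface(F: np.ndarray) -> np.ndarray:
    F = np.asarray(F, dtype=float)
    if F.ndim != 2:
        raise ValueError("en-face image must be 2-D")
    if F.min() < -1e-9 or F.max() > DYNAMIC_RANGE + 1e-9:
        raise ValueError("en-face image must lie in [0, 255]")
    return F


def compute_flux(F: np.ndarray, disc_mask: np.ndarray) -> float:
    """Mean normalized flow over the disc: sum of F/255 over disc pixels
    divided by the disc pixel count."""
    F = _check_enface(F)
    disc = np.asarray(disc_mask, dtype=bool)
    if disc.shape != F.shape:
        raise ValueError("disc mask shape differs from image")
    if not disc.any():
        raise ValueError("empty disc mask")
    return float((F[disc] / DYNAMIC_RANGE).mean())


def compute_vessel_area_density(vessel_mask: np.ndarray, disc_mask: np.ndarray) -> float:
    """Fraction of the disc area occupied by detected vessels."""
    vessel = np.asarray(vessel_mask, dtype=bool)
    disc = np.asarray(disc_mask, dtype=bool)
    if vessel.shape != disc.shape:
        raise ValueError("mask shapes differ")
    if not disc.any():
        raise ValueError("empty disc mask")
    return float((vessel & disc).sum() / disc.sum())


def compute_normalized_flux(
    F: np.ndarray, vessel_mask: np.ndarray, disc_mask: np.ndarray
) -> float:
    """Mean normalized flow over vessel pixels inside the disc.

    With no vessel pixels the quantity is undefined: NaN is returned with
    a warning (a zero would fake perfect ischemia and corrupt group means).
    """
    F = _check_enface(F)
    vessel = np.asarray(vessel_mask, dtype=bool)
    disc = np.asarray(disc_mask, dtype=bool)
    sel = vessel & disc
    if not sel.any():
        warnings.warn("no vessel pixels inside the disc; normalized flux undefined")
        return float("nan")
    return float((F[sel] / DYNAMIC_RANGE).mean())


def compute_perfusion_metrics(
    F: np.ndarray, vessel_mask: np.ndarray, disc_mask: np.ndarray
) -> PerfusionMetrics:
    """All three metrics plus the pixel areas, in one pass."""
    flux = compute_flux(F, disc_mask)
    density = compute_vessel_area_density(vessel_mask, disc_mask)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        nf = compute_normalized_flux(F, vessel_mask, disc_mask)
    defined = not np.isnan(nf)
    disc = np.asarray(disc_mask, dtype=bool)
    vessel = np.asarray(vessel_mask, dtype=bool)
    return PerfusionMetrics(
        flux=flux,
        vessel_area_density=density,
        normalized_flux=nf,
        area_onh_px=int(disc.sum()),
        vessel_area_px=int((vessel & disc).sum()),
        normalized_flux_defined=defined,
    )


def qc_filter(
    records: pd.DataFrame,
    signal_cutoff: float = QC_SIGNAL_CUTOFF,
    strength_col: str = "signal_strength",
    motion_col: str = "motion_flag",
    group_col: str = "group",
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Partition scans into included / excluded by the study QC rule.

    A record is excluded iff its signal strength is below ``signal_cutoff``
    (strictly: strength 5 is excluded, 6 is included) or its motion flag is
    set.  A missing strength is treated as excluded with a warning.
    Returns ``(included, excluded, counts)`` where ``counts`` tabulates
    enrolled / excluded / included per group.
    """
    df = records.copy()
    strength = pd.to_numeric(df[strength_col], errors="coerce")
    if strength.notna().any() and ((strength.dropna() < 0) | (strength.dropna() > 10)).any():
        raise ValueError("signal strength must lie in [0, 10]")
    missing = strength.isna()
    if missing.any():
        warnings.warn(f"{int(missing.sum())} record(s) missing signal strength; excluded")
    motion = df[motion_col].fillna(False).astype(bool) if motion_col in df else False
    excluded_mask = missing | (strength < signal_cutoff) | motion
    included = df[~excluded_mask]
    excluded = df[excluded_mask]
    if group_col in df:
        counts = pd.DataFrame({
            "enrolled": df.groupby(group_col).size(),
            "excluded": df[excluded_mask].groupby(group_col).size(),
        }).fillna(0).astype(int)
        counts["included"] = counts["enrolled"] - counts["excluded"]
    else:
        counts = pd.DataFrame({
            "enrolled": [len(df)],
            "excluded": [int(excluded_mask.sum())],
            "included": [int((~excluded_mask).sum())],
        })
    return included, excluded, counts
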