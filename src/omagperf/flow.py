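"""OMAG blood-flow signal from repeated complex B-scans.

At every slow-axis location the scanner acquires ``R`` consecutive B-scans
of the same tissue cross-section.  Backscatter from static tissue is stable
between repeats while backscatter from moving red blood cells decorrelates,
so the magnitude of the complex difference between consecutive repeats is a
flow contrast.  The flow signal at A-scan ``x`` and depth ``z`` is the
average of the ``R - 1`` consecutive-pair difference magnitudes:

    I_flow(x, z) = 1/(R-1) * sum_i |C_{i+1}(x, z) - C_i(x, z)|

The raw flow signal is mapped onto the 0-255 dynamic range used by the
en-face display and by the perfusion metrics (which divide by 255).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RepeatedBScanVolume",
    "FlowVolume",
    "compute_flow",
    "scale_to_dynamic_range",
    "inter_bscan_period_ms",
]

#: Full dynamic range of the displayed flow signal.
DYNAMIC_RANGE = 255.0


@dataclass
class RepeatedBScanVolume:
    """Complex OCT signal for a repeated-B-scan protocol.

    Parameters
    ----------
    data
        Complex array of shape ``(ny, R, nx, nz)``: slow-axis location,
        repeat index, A-scan within the B-scan, depth sample.
    extent_mm
        Physical (fast, slow) scan extent in millimetres.
    ascan_rate_hz
        A-scan acquisition rate of the instrument.
    seed
        Seed used to generate the volume, if synthetic.
    """

    data: np.ndarray
    extent_mm: tuple[float, float] = (2.4, 2.4)
    ascan_rate_hz: float = 68_000.0
    seed: int | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(
                f"expected 4-D (ny, R, nx, nz) array, got shape {self.data.shape}"
            )
        if self.repeats < 2:
            raise ValueError(f"need at least 2 repeated B-scans, got R={self.repeats}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("complex OCT volume contains non-finite values")

    @property
    def ny(self) -> int:
        return self.data.shape[0]

    @property
    def repeats(self) -> int:
        return self.data.shape[1]

    @property
    def nx(self) -> int:
        return self.data.shape[2]

    @property
    def nz(self) -> int:
        return self.data.shape[3]

    def inter_bscan_period_ms(self) -> float:
        """Time between consecutive repeated B-scans, in milliseconds."""
        return inter_bscan_period_ms(self.nx, self.ascan_rate_hz)


@dataclass
class FlowVolume:
    """Real-valued flow signal ``I_flow(x, y, z)``.

    ``scaled`` is False while the volume carries raw ``|dC|`` units and True
    once it has been mapped onto [0, 255]; ``scale_factor`` records the
    multiplicative factor applied (0 for a degenerate all-zero volume).
    """

    data: np.ndarray
    scaled: bool = False
    scale_factor: float | None = None
    scale_mode: str | None = None
    extent_mm: tuple[float, float] = (2.4, 2.4)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3-D (nx, ny, nz) array, got {self.data.shape}")
        if np.any(self.data < 0):
            raise ValueError("flow signal must be nonnegative")
        if self.scaled and self.data.size and self.data.max() > DYNAMIC_RANGE + 1e-9:
            raise ValueError("scaled flow exceeds the 0-255 dynamic range")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


def inter_bscan_period_ms(ascans_per_bscan: int, ascan_rate_hz: float) -> float:
    """Inter-B-scan period implied by the scan protocol.

    One B-scan of ``ascans_per_bscan`` A-scans acquired at ``ascan_rate_hz``
    takes ``ascans_per_bscan / ascan_rate_hz`` seconds, which is the time
    separating consecutive repeats at a fixed transversal location (245
    A-scans at 68 kHz gives ~3.6 ms).
    """
    if ascans_per_bscan <= 0 or ascan_rate_hz <= 0:
        raise ValueError("A-scan count and rate must be positive")
    return 1000.0 * ascans_per_bscan / ascan_rate_hz


def compute_flow(vol: RepeatedBScanVolume) -> FlowVolume:
    """Average consecutive-pair complex difference magnitude per voxel.

    Returns a raw (unscaled) :class:`FlowVolume` with shape ``(nx, ny, nz)``.
    Identical repeats give exactly zero flow; a global phase rotation of all
    repeats leaves the result unchanged.
    """
    c = vol.data
    # (ny, R-1, nx, nz) pairwise magnitudes, averaged over the pair axis
    dmag = np.abs(np.diff(c, axis=1))
    flow_yxz = dmag.mean(axis=1)
    flow = np.ascontiguousarray(np.moveaxis(flow_yxz, 0, 1))  # (nx, ny, nz)
    return FlowVolume(
        data=flow,
        scaled=False,
        extent_mm=vol.extent_mm,
        meta={"repeats": vol.repeats},
    )


def scale_to_dynamic_range(
    flow: FlowVolume,
    mode: str = "percentile",
    percentile: float = 99.5,
    factor: float | None = None,
) -> FlowVolume:
    """Map a raw flow volume affinely onto [0, 255].

    Parameters
    ----------
    mode
        ``"max"`` divides by the volume maximum, ``"percentile"`` clips at
        the given upper percentile before scaling (robust to single-voxel
        outliers; the default), and ``"fixed"`` applies an explicit
        ``factor`` — used when several volumes must share one intensity
        mapping so their metrics are comparable.
    percentile
        Upper clip percentile for ``mode="percentile"``.
    factor
        Multiplicative scale for ``mode="fixed"`` (raw units -> 0-255).

    An all-zero volume is returned unchanged with ``scale_factor=0`` so the
    degenerate case is visible to callers.
    """
    if flow.scaled:
        raise ValueError("flow volume is already scaled to the dynamic range")
    raw = flow.data
    if mode == "fixed":
        if factor is None or factor <= 0:
            raise ValueError("mode='fixed' requires a positive scale factor")
        scaled = np.clip(raw * factor, 0.0, DYNAMIC_RANGE)
        return FlowVolume(scaled, scaled=True, scale_factor=factor,
                          scale_mode=mode, extent_mm=flow.extent_mm,
                          meta=dict(flow.meta))
    if mode == "max":
        ref = float(raw.max()) if raw.size else 0.0
    elif mode == "percentile":
        if not 0 < percentile <= 100:
            raise ValueError("percentile must be in (0, 100]")
        ref = float(np.percentile(raw, percentile)) if raw.size else 0.0
    else:
        raise ValueError(f"unknown scaling mode {mode!r}")
    if ref <= 0:
        # all-zero (or empty) volume: nothing to scale
        return FlowVolume(raw.copy(), scaled=True, scale_factor=0.0,
                          scale_mode=mode, extent_mm=flow.extent_mm,
                          meta={**flow.meta, "degenerate": True})
    sf = DYNAMIC_RANGE / ref
    scaled = np.clip(raw * sf, 0.0, DYNAMIC_RANGE)
    return FlowVolume(scaled, scaled=True, scale_factor=sf, scale_mode=mode,
                      extent_mm=flow.extent_mm, meta=dict(flow.meta))
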