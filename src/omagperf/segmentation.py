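"""Layer segmentation and disc-margin delineation on structural volumes.

The pre-laminar slab is bounded above by the inner limiting membrane (ILM,
the vitreoretinal interface — the first strong axial intensity gradient)
and below by one continuous surface that is the RPE/Bruch's membrane
complex outside the disc and the anterior lamina cribrosa within it (the
strongest gradient below the ILM).  The disc margin is where the bright
RPE/BM band terminates: per B-scan the band is traced inward from both
edges, the termination points are collected over all B-scans, and an
ellipse fit to the termini defines the en-face disc mask.

All automatic results can be overridden by manual surfaces or contours
(the "semi-automatic" mode): overrides always win, bit-exact.  Coordinates
are 0-based, depth increases with z, and depth intervals are half-open
``[z_ilm, z_alc)`` so voxel counting is unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.draw import polygon as _sk_polygon
from skimage.measure import EllipseModel

__all__ = [
    "LayerModel",
    "SegmentationError",
    "segment_layers",
    "delineate_disc_margin",
    "prelc_mask",
    "surface_from_control_points",
    "rasterize_polygon",
]


class SegmentationError(RuntimeError):
    """Raised when automatic segmentation fails; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclass
class LayerModel:
    """ILM and anterior-LC/RPE surfaces plus the en-face disc mask."""

    z_ilm: np.ndarray                      # (nx, ny) float depth samples
    z_alc: np.ndarray                      # (nx, ny)
    disc_mask: np.ndarray | None = None    # (nx, ny) bool
    disc_contour: np.ndarray | None = None # (K, 2) ellipse/polygon vertices
    extent_mm: tuple[float, float] = (2.4, 2.4)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.z_ilm = np.asarray(self.z_ilm, dtype=float)
        self.z_alc = np.asarray(self.z_alc, dtype=float)
        if self.z_ilm.shape != self.z_alc.shape:
            raise ValueError("surface shapes differ")
        if np.any(self.z_ilm > self.z_alc):
            raise ValueError("ILM must not lie below the anterior LC surface")
        if self.disc_mask is not None:
            self.disc_mask = np.asarray(self.disc_mask, dtype=bool)
            if self.disc_mask.shape != self.z_ilm.shape:
                raise ValueError("disc mask shape differs from surfaces")

    @property
    def shape(self) -> tuple[int, int]:
        return self.z_ilm.shape

    def area_onh_px(self) -> int:
        """Disc area as an en-face pixel count."""
        if self.disc_mask is None:
            raise ValueError("no disc mask delineated yet")
        return int(self.disc_mask.sum())

    def area_onh_mm2(self) -> float:
        nx, ny = self.shape
        px_area = (self.extent_mm[0] / nx) * (self.extent_mm[1] / ny)
        return self.area_onh_px() * px_area


def _deepest_near_max(g: np.ndarray, lo: int, hi: int, rel_tol: float = 1e-9) -> int:
    """Index of the maximum of g[lo:hi]; ties (within rel_tol of the max)
    resolved toward the deeper sample, fixing the half-sample ambiguity of
    a symmetric step edge in favour of the first sample at/below it."""
    seg = g[lo:hi]
    m = seg.max()
    close = np.nonzero(seg >= m - rel_tol * max(abs(m), 1.0))[0]
    return lo + int(close[-1])


def surface_from_control_points(
    points: np.ndarray, shape: tuple[int, int], smoothing: float = 0.0
) -> np.ndarray:
    """Interpolate a manual (x, y, z) control-point set to a full surface
    by thin-plate-spline interpolation."""
    from scipy.interpolate import RBFInterpolator

    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 3:
        raise ValueError("control points must be (K, 3) of (x, y, z)")
    interp = RBFInterpolator(points[:, :2], points[:, 2],
                             kernel="thin_plate_spline", smoothing=smoothing)
    nx, ny = shape
    gx, gy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    return interp(np.column_stack([gx.ravel(), gy.ravel()])).reshape(nx, ny)


def segment_layers(
    structural: np.ndarray,
    smooth_sigma: float = 2.0,
    threshold_nsd: float = 2.0,
    min_separation: int = 4,
    median_size: int = 3,
    max_failed_fraction: float = 0.05,
    ilm_override: np.ndarray | None = None,
    alc_override: np.ndarray | None = None,
    extent_mm: tuple[float, float] = (2.4, 2.4),
) -> LayerModel:
    """Delineate the ILM and anterior-LC/RPE surfaces per A-scan.

    Per A-scan the intensity profile is Gaussian-smoothed along depth
    (``smooth_sigma`` samples), differentiated by central differences, and
    the ILM is placed at the first depth where the gradient exceeds an
    adaptive threshold (mean + ``threshold_nsd`` SD of that A-scan's
    gradient), refined to the gradient peak with ties broken toward the
    deeper sample.  The anterior-LC/RPE surface is the strongest absolute
    gradient at least ``min_separation`` samples below the ILM.  Both
    surfaces are median-filtered across the en-face plane and the ordering
    invariant is enforced.  Manual override surfaces are returned verbatim.

    Raises :class:`SegmentationError` (with per-A-scan diagnostics) when
    more than ``max_failed_fraction`` of A-scans have no gradient above
    threshold.
    """
    vol = np.asarray(structural, dtype=float)
    if vol.ndim != 3:
        raise ValueError("structural volume must be 3-D (nx, ny, nz)")
    if not np.all(np.isfinite(vol)) or np.any(vol < 0):
        raise ValueError("structural volume must be finite and nonnegative")
    nx, ny, nz = vol.shape

    if ilm_override is not None and alc_override is not None:
        return LayerModel(np.asarray(ilm_override, float),
                          np.asarray(alc_override, float),
                          extent_mm=extent_mm, meta={"override": "both"})

    sm = ndimage.gaussian_filter1d(vol, smooth_sigma, axis=2, mode="nearest")
    grad = np.gradient(sm, axis=2)

    mu = grad.mean(axis=2, keepdims=True)
    sd = grad.std(axis=2, keepdims=True)
    above = grad > mu + threshold_nsd * sd

    z_ilm = np.full((nx, ny), np.nan)
    z_alc = np.full((nx, ny), np.nan)
    failed = np.zeros((nx, ny), dtype=bool)
    for i in range(nx):
        for j in range(ny):
            hits = np.nonzero(above[i, j])[0]
            if hits.size == 0:
                failed[i, j] = True
                continue
            first = int(hits[0])
            # refine to the local gradient peak just below the crossing
            hi = min(first + 2 * int(np.ceil(smooth_sigma)) + 3, nz)
            zi = _deepest_near_max(grad[i, j], first, hi)
            z_ilm[i, j] = zi
            lo = min(zi + min_separation, nz - 1)
            z_alc[i, j] = _deepest_near_max(np.abs(grad[i, j]), lo, nz)

    frac_failed = failed.mean()
    if frac_failed > max_failed_fraction:
        raise SegmentationError(
            f"{frac_failed:.1%} of A-scans had no gradient above threshold",
            diagnostics={"failed_mask": failed},
        )
    if failed.any():
        # fill isolated failures from the median of their neighbourhood
        for surf in (z_ilm, z_alc):
            filled = ndimage.generic_filter(
                np.nan_to_num(surf, nan=np.nanmedian(surf)), np.median, size=5
            )
            surf[failed] = filled[failed]

    if median_size > 1:
        z_ilm = ndimage.median_filter(z_ilm, size=median_size, mode="nearest")
        z_alc = ndimage.median_filter(z_alc, size=median_size, mode="nearest")
    z_alc = np.maximum(z_alc, z_ilm)

    if ilm_override is not None:
        z_ilm = np.asarray(ilm_override, float)
        z_alc = np.maximum(z_alc, z_ilm)
    if alc_override is not None:
        z_alc = np.asarray(alc_override, float)
        z_ilm = np.minimum(z_ilm, z_alc)
    return LayerModel(z_ilm, z_alc, extent_mm=extent_mm,
                      meta={"failed_fraction": float(frac_failed)})


def rasterize_polygon(vertices: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize a closed (x, y) polygon to a boolean en-face mask."""
    vertices = np.asarray(vertices, dtype=float)
    rr, cc = _sk_polygon(vertices[:, 0], vertices[:, 1], shape=shape)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return mask


def _ellipse_mask(params, shape: tuple[int, int]) -> np.ndarray:
    xc, yc, a, b, theta = params
    nx, ny = shape
    gx, gy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    ct, st = np.cos(theta), np.sin(theta)
    u = (gx - xc) * ct + (gy - yc) * st
    v = -(gx - xc) * st + (gy - yc) * ct
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def delineate_disc_margin(
    structural: np.ndarray,
    layers: LayerModel,
    band_px: int = 5,
    presence_ratio: float = 0.75,
    min_termini: int = 6,
    manual_contour: np.ndarray | None = None,
) -> LayerModel:
    """Locate the disc margin at the termination of Bruch's membrane.

    For every en-face pixel the peak intensity within a small window around
    the anterior-LC/RPE surface is measured; the bright RPE/BM band is
    declared present where this peak exceeds ``presence_ratio`` times the
    reference band brightness at the scan edges.  Per B-scan the band is
    traced from each lateral edge toward the centre and the termination
    recorded at the midpoint between the last present and first absent
    pixel.  An ellipse is fit to all termini (at least ``min_termini``
    required) and its interior becomes the disc mask.

    A ``manual_contour`` polygon, if given, is rasterized and used instead
    of the automatic fit.
    """
    vol = np.asarray(structural, dtype=float)
    nx, ny, nz = vol.shape
    if layers.shape != (nx, ny):
        raise ValueError("layer model does not match the volume")

    if manual_contour is not None:
        mask = rasterize_polygon(manual_contour, (nx, ny))
        return LayerModel(layers.z_ilm, layers.z_alc, disc_mask=mask,
                          disc_contour=np.asarray(manual_contour, float),
                          extent_mm=layers.extent_mm,
                          meta={**layers.meta, "disc": "manual"})

    z = np.arange(nz)[None, None, :]
    alc = layers.z_alc[:, :, None]
    # symmetric window: the fitted surface may sit at either flank of the
    # bright band, so search band_px+2 samples on both sides
    window = (z >= alc - band_px - 2) & (z <= alc + band_px + 2)
    band_peak = np.where(window, vol, -np.inf).max(axis=2)
    # speckle makes the band peak fluctuate; smooth laterally before
    # thresholding so isolated fades do not mimic a termination
    band_peak = ndimage.median_filter(band_peak, size=3, mode="nearest")

    edge_cols = np.r_[band_peak[:3, :].ravel(), band_peak[-3:, :].ravel()]
    ref = np.median(edge_cols)
    present = band_peak > presence_ratio * ref

    # a terminus needs a sustained absence (>= 3 px) to reject residual
    # speckle dropouts
    absent = ~present
    run3 = absent[:-2, :] & absent[1:-1, :] & absent[2:, :]
    termini = []
    for j in range(ny):
        runs = np.nonzero(run3[:, j])[0]
        if runs.size == 0 or present[:, j].all() or not present[:, j].any():
            continue
        left, right = runs[0], runs[-1] + 2
        if left > 0:
            termini.append((left - 0.5, float(j)))
        if right < nx - 1:
            termini.append((right + 0.5, float(j)))
    if len(termini) < min_termini:
        raise SegmentationError(
            f"only {len(termini)} Bruch's membrane termini found; "
            "ellipse fit underdetermined (no disc in scene?)",
            diagnostics={"termini": termini},
        )
    pts = np.asarray(termini)
    try:
        # RANSAC: residual speckle dropouts outside the disc create a few
        # outlier termini that skew a direct conic fit
        from skimage.measure import ransac as _ransac

        model, inliers = _ransac(pts, EllipseModel, min_samples=5,
                                 residual_threshold=2.0, max_trials=200,
                                 rng=0)
        if model is None:
            raise ValueError("RANSAC found no consensus")
        if hasattr(model, "center"):
            params = (*model.center, *model.axis_lengths, model.theta)
        else:
            params = tuple(model.params)
    except Exception as e:
        raise SegmentationError(f"ellipse fit to BM termini failed: {e}",
                                diagnostics={"termini": termini}) from e
    mask = _ellipse_mask(params, (nx, ny))
    if not mask.any():
        raise SegmentationError("fitted ellipse contains no pixels")
    return LayerModel(layers.z_ilm, layers.z_alc, disc_mask=mask,
                      disc_contour=model.predict_xy(np.linspace(0, 2 * np.pi, 180)),
                      extent_mm=layers.extent_mm,
                      meta={**layers.meta, "disc": "auto",
                            "ellipse_params": tuple(map(float, params)),
                            "n_termini": len(termini)})


def prelc_mask(layers: LayerModel, nz: int) -> np.ndarray:
    """3-D boolean mask of the pre-laminar slab.

    Voxel (x, y, z) is selected iff the disc mask is true at (x, y) and
    ``z_ilm(x, y) <= z < z_alc(x, y)`` (half-open in depth, so a pixel with
    coincident surfaces contributes no voxels).
    """
    if layers.disc_mask is None:
        raise ValueError("layer model has no disc mask")
    z = np.arange(nz)[None, None, :]
    slab = (z >= layers.z_ilm[:, :, None]) & (z < layers.z_alc[:, :, None])
    return slab & layers.disc_mask[:, :, None]
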