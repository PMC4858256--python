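"""Synthetic repeated-B-scan OCT volumes and simulated cohorts.

Two generators:

* :func:`generate_volume` builds a complex repeated-B-scan volume with a
  known anatomy (tilted inner limiting membrane, a deeper RPE / anterior
  lamina cribrosa surface, a circular disc where Bruch's membrane
  terminates) and a vessel tree whose voxels decorrelate between repeats.
  Static voxels keep an identical noiseless complex signal across repeats;
  vessel voxels are re-drawn per repeat with a phase spread controlled by a
  per-vessel decorrelation magnitude ``delta`` in [0, 1], plus amplitude
  jitter proportional to ``delta``.  Complex Gaussian noise is added per
  repeat.  The ground truth (3-D vessel mask, surfaces, disc mask, en-face
  vessel fraction) is returned alongside.

* :func:`generate_cohort` draws per-eye records from group-specific
  multivariate Gaussians (normal / POAG / NTG) with configurable means,
  SDs and correlations, producing the covariate table the statistics stage
  consumes.  Mean ocular perfusion pressure is computed from the simulated
  blood pressures and IOP rather than drawn independently, so it is always
  internally consistent with the MOPP formula.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .flow import RepeatedBScanVolume
from .stats import compute_mopp

__all__ = [
    "Vessel",
    "SceneSpec",
    "GroundTruth",
    "CohortSpec",
    "generate_volume",
    "generate_cohort",
    "make_scene",
    "default_cohort_spec",
    "nearest_correlation",
]

GROUPS = ("normal", "POAG", "NTG")


@dataclass
class Vessel:
    """A vessel as an en-face centerline polyline with a tube radius.

    ``path`` is an (M, 2) float array of (x, y) pixel coordinates;
    ``radius_px`` the tube radius; ``delta`` the inter-repeat decorrelation
    magnitude in [0, 1]; ``depth_frac`` the vessel's depth within the
    pre-laminar slab (0 = at the ILM, 1 = at the anterior LC).
    """

    path: np.ndarray
    radius_px: float = 3.0
    delta: float = 1.0
    depth_frac: float = 0.5

    def __post_init__(self) -> None:
        self.path = np.atleast_2d(np.asarray(self.path, dtype=float))
        if self.path.shape[1] != 2:
            raise ValueError("vessel path must be (M, 2) of (x, y) points")
        if not 0.0 <= self.delta <= 1.0:
            raise ValueError(f"decorrelation delta must be in [0, 1], got {self.delta}")
        if self.radius_px <= 0:
            raise ValueError("vessel radius must be positive")


@dataclass
class SceneSpec:
    """Everything needed to synthesise one repeated-B-scan volume."""

    nx: int = 128
    ny: int = 128
    nz: int = 256
    repeats: int = 4
    extent_mm: tuple[float, float] = (2.4, 2.4)
    z_ilm: np.ndarray | float = 40.0
    z_alc: np.ndarray | float = 110.0
    disc_radius_mm: float = 0.75
    disc_center_mm: tuple[float, float] | None = None
    vessels: list[Vessel] = field(default_factory=list)
    tissue_reflectivity: float = 0.5
    vessel_reflectivity: float = 0.6
    rpe_reflectivity: float = 1.0
    sub_rpe_reflectivity: float = 0.55
    lamina_reflectivity: float = 0.15
    rpe_band_px: int = 4
    noise_sd: float = 0.02
    amplitude_jitter: float = 0.2
    psf_sigma_px: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.nx, self.ny, self.nz) < 4:
            raise ValueError("grid dimensions must be at least 4 samples")
        if self.repeats < 2:
            raise ValueError("need at least 2 repeated B-scans")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be nonnegative")
        if not 0 < self.disc_radius_mm < min(self.extent_mm) / 2:
            raise ValueError("disc radius must be positive and < half scan extent")
        self.z_ilm = self._surface(self.z_ilm)
        self.z_alc = self._surface(self.z_alc)
        if np.any(self.z_ilm < 0) or np.any(self.z_alc >= self.nz):
            raise ValueError("layer surfaces must lie within [0, nz)")
        if np.any(self.z_ilm >= self.z_alc):
            raise ValueError("ILM must be strictly above the anterior LC everywhere")

    def _surface(self, z) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        if z.ndim == 0:
            z = np.full((self.nx, self.ny), float(z))
        if z.shape != (self.nx, self.ny):
            raise ValueError(f"surface shape {z.shape} != (nx, ny)")
        return z

    @property
    def px_per_mm(self) -> tuple[float, float]:
        return self.nx / self.extent_mm[0], self.ny / self.extent_mm[1]

    def disc_mask(self) -> np.ndarray:
        """True en-face disc mask (ellipse in pixels from the mm radius)."""
        cx_mm, cy_mm = self.disc_center_mm or (self.extent_mm[0] / 2, self.extent_mm[1] / 2)
        sx, sy = self.px_per_mm
        x = (np.arange(self.nx) + 0.5) / sx
        y = (np.arange(self.ny) + 0.5) / sy
        dx = (x[:, None] - cx_mm)
        dy = (y[None, :] - cy_mm)
        return dx ** 2 + dy ** 2 <= self.disc_radius_mm ** 2


@dataclass
class GroundTruth:
    """Known truth for a synthetic scene (artifact plumbing)."""

    vessel_mask: np.ndarray          # (nx, ny, nz) bool
    decorrelation: np.ndarray        # (nx, ny, nz) per-voxel delta
    z_ilm: np.ndarray                # (nx, ny)
    z_alc: np.ndarray                # (nx, ny)
    disc_mask: np.ndarray            # (nx, ny) bool
    enface_vessel_mask: np.ndarray   # (nx, ny) bool, slab projection
    vessel_fraction: float           # en-face vessel fraction inside the disc

    def __post_init__(self) -> None:
        if not 0.0 <= self.vessel_fraction <= 1.0:
            raise ValueError("vessel fraction must be in [0, 1]")


def _rasterize_vessel_footprint(vessel: Vessel, nx: int, ny: int) -> np.ndarray:
    """En-face boolean footprint of a vessel tube (dilated centerline)."""
    # densify the polyline to ~0.5 px steps, then threshold the distance
    # to the sample points over a bounding box around the path
    pts = vessel.path
    if len(pts) > 1:
        seg = np.diff(pts, axis=0)
        seglen = np.hypot(seg[:, 0], seg[:, 1])
        dense = [pts[:1]]
        for p, s, L in zip(pts[:-1], seg, seglen):
            n = max(int(np.ceil(L / 0.5)), 1)
            t = np.linspace(0, 1, n + 1)[1:, None]
            dense.append(p[None, :] + t * s[None, :])
        pts = np.vstack(dense)
    mask = np.zeros((nx, ny), dtype=bool)
    r = vessel.radius_px
    xi = np.arange(nx)
    yi = np.arange(ny)
    x0 = max(int(np.floor(pts[:, 0].min() - r - 1)), 0)
    x1 = min(int(np.ceil(pts[:, 0].max() + r + 1)) + 1, nx)
    y0 = max(int(np.floor(pts[:, 1].min() - r - 1)), 0)
    y1 = min(int(np.ceil(pts[:, 1].max() + r + 1)) + 1, ny)
    if x0 >= x1 or y0 >= y1:
        return mask
    gx = xi[x0:x1][:, None, None]
    gy = yi[y0:y1][None, :, None]
    d2 = (gx - pts[None, None, :, 0]) ** 2 + (gy - pts[None, None, :, 1]) ** 2
    mask[x0:x1, y0:y1] = d2.min(axis=2) <= r ** 2
    return mask


def _build_anatomy(spec: SceneSpec):
    """Static amplitude field plus vessel masks from the scene geometry."""
    nx, ny, nz = spec.nx, spec.ny, spec.nz
    z = np.arange(nz)[None, None, :]
    ilm = spec.z_ilm[:, :, None]
    alc = spec.z_alc[:, :, None]
    disc = spec.disc_mask()

    amp = np.zeros((nx, ny, nz))
    tissue = (z >= ilm) & (z < alc)
    amp[tissue] = spec.tissue_reflectivity
    band = (z >= alc) & (z < alc + spec.rpe_band_px)
    below = z >= alc + spec.rpe_band_px
    out = ~disc[:, :, None]
    # Bruch's membrane / RPE band exists only outside the disc margin;
    # inside the disc the anterior lamina cribrosa backscatters weakly.
    amp[band & out] = spec.rpe_reflectivity
    amp[below & out] = spec.sub_rpe_reflectivity
    amp[(band | below) & ~out] = spec.lamina_reflectivity

    vessel_mask = np.zeros((nx, ny, nz), dtype=bool)
    decorrelation = np.zeros((nx, ny, nz))
    for v in spec.vessels:
        foot = _rasterize_vessel_footprint(v, nx, ny)
        if not foot.any():
            continue
        zc = spec.z_ilm + v.depth_frac * (spec.z_alc - spec.z_ilm)
        tube = (np.abs(z - zc[:, :, None]) <= v.radius_px) & foot[:, :, None] & tissue
        vessel_mask |= tube
        decorrelation[tube] = np.maximum(decorrelation[tube], v.delta)
    amp[vessel_mask] = spec.vessel_reflectivity
    return amp, vessel_mask, decorrelation, disc


def generate_volume(spec: SceneSpec) -> tuple[RepeatedBScanVolume, GroundTruth]:
    """Synthesise a repeated-B-scan complex volume and its ground truth.

    Static voxels share one speckle-like complex value across all repeats;
    a vessel voxel with decorrelation ``delta`` gets, per repeat ``k``, the
    signal ``A_k * exp(i * phi_k)`` with ``phi_k`` uniform on
    ``[0, 2*pi*delta]`` (re-drawn independently each repeat) and
    ``A_k = A * (1 + jitter * delta * eta_k)`` an amplitude jitter.  The
    same seed therefore reuses the same underlying uniforms across scenes
    that differ only in ``delta``, making the mean flow over vessel voxels
    monotone in ``delta``.

    The lateral beam-waist blur (``psf_sigma_px``) is applied to the
    reflectivity map before the speckle phase is attached — an incoherent
    PSF model, consistent with treating rigorous coherent speckle
    formation as out of scope.  It keeps static voxels bit-identical
    across repeats regardless of the PSF, and confines inter-repeat
    decorrelation exactly to the vessel tubes.  Additive complex Gaussian
    noise (SD per real component ``noise_sd / sqrt(2)``) is applied per
    repeat last.
    """
    rng = np.random.default_rng(spec.seed)
    amp, vessel_mask, decorrelation, disc = _build_anatomy(spec)
    nx, ny, nz, R = spec.nx, spec.ny, spec.nz, spec.repeats

    if spec.psf_sigma_px > 0:
        from scipy import ndimage

        amp = ndimage.gaussian_filter(
            amp, (spec.psf_sigma_px, spec.psf_sigma_px, 0.0))

    # static speckle phase, fixed across repeats
    phase0 = rng.uniform(0.0, 2 * np.pi, size=(nx, ny, nz))
    base = amp * np.exp(1j * phase0)

    data = np.empty((ny, R, nx, nz), dtype=np.complex128)
    vm = vessel_mask
    n_v = int(vm.sum())
    vamp = amp[vm]
    vdelta = decorrelation[vm]
    for k in range(R):
        frame = base.copy()
        if n_v:
            u = rng.uniform(0.0, 1.0, size=n_v)
            eta = rng.standard_normal(n_v)
            a_k = vamp * np.clip(1.0 + spec.amplitude_jitter * vdelta * eta, 0.1, None)
            frame[vm] = a_k * np.exp(1j * (2 * np.pi * vdelta * u))
        if spec.noise_sd > 0:
            noise = rng.standard_normal((nx, ny, nz)) + 1j * rng.standard_normal((nx, ny, nz))
            frame = frame + spec.noise_sd / np.sqrt(2.0) * noise
        data[:, k, :, :] = np.moveaxis(frame, 1, 0)  # (ny, nx, nz)

    vol = RepeatedBScanVolume(data=data, extent_mm=spec.extent_mm, seed=spec.seed)
    enface_vessels = vessel_mask.any(axis=2)
    n_disc = int(disc.sum())
    frac = float((enface_vessels & disc).sum() / n_disc) if n_disc else 0.0
    gt = GroundTruth(
        vessel_mask=vessel_mask,
        decorrelation=decorrelation,
        z_ilm=spec.z_ilm.copy(),
        z_alc=spec.z_alc.copy(),
        disc_mask=disc,
        enface_vessel_mask=enface_vessels,
        vessel_fraction=frac,
    )
    return vol, gt


def make_scene(
    nx: int = 128,
    ny: int = 128,
    nz: int = 192,
    repeats: int = 4,
    target_vessel_fraction: float = 0.5,
    delta: float = 1.0,
    vessel_radius_px: tuple[float, float] = (3.0, 4.0),
    ilm_depth: float | None = None,
    ilm_tilt: tuple[float, float] = (8.0, 4.0),
    slab_thickness: float | None = None,
    cup_depth: float | None = None,
    disc_radius_mm: float = 0.75,
    noise_sd: float = 0.02,
    seed: int = 0,
) -> SceneSpec:
    """Build a realistic default scene: tilted ILM, cupped anterior LC,
    a circular disc, and a bundle of non-overlapping wavy vessels running
    roughly vertically across the scan (the superior/inferior course of
    the central retinal vessel branches).  The lateral spacing between
    tubes is computed from ``target_vessel_fraction`` so the en-face fill
    inside the disc lands near the request; vasculature remains tubular at
    every fill instead of merging into blobs.

    Vessel radii of 3-4 px correspond to 60-80 um diameter vessels at the
    ~10 um/px sampling of a 2.4 mm scan with 245 locations — the calibre
    of the arteriolar/venular branches that dominate the pre-laminar
    en-face angiogram.
    """
    rng = np.random.default_rng(seed)
    # depth geometry scales with the axial sampling unless given explicitly
    if ilm_depth is None:
        ilm_depth = 0.20 * nz
    if slab_thickness is None:
        slab_thickness = 0.35 * nz
    if cup_depth is None:
        cup_depth = 0.05 * nz
    xg = np.arange(nx)[:, None] / max(nx - 1, 1)
    yg = np.arange(ny)[None, :] / max(ny - 1, 1)
    z_ilm = ilm_depth + ilm_tilt[0] * xg + ilm_tilt[1] * yg
    z_alc = z_ilm + slab_thickness

    spec = SceneSpec(
        nx=nx, ny=ny, nz=nz, repeats=repeats,
        z_ilm=z_ilm, z_alc=np.broadcast_to(z_alc, (nx, ny)).copy(),
        disc_radius_mm=disc_radius_mm, noise_sd=noise_sd, seed=seed,
    )
    disc = spec.disc_mask()
    # shallow cup: deepen the anterior LC smoothly inside the disc
    if cup_depth > 0:
        sx, sy = spec.px_per_mm
        cx = nx / 2.0
        cy = ny / 2.0
        r_px = disc_radius_mm * sx
        d = np.hypot((np.arange(nx)[:, None] - cx), (np.arange(ny)[None, :] - cy))
        bowl = cup_depth * np.clip(1 - (d / r_px) ** 2, 0, None)
        spec.z_alc = np.minimum(spec.z_alc + bowl, nz - spec.rpe_band_px - 2)

    if not 0 < target_vessel_fraction < 0.85:
        raise ValueError("target vessel fraction must lie in (0, 0.85)")
    # lateral gap between tube edges that yields the requested fill for
    # the mean radius: fill = 2*rbar / (2*rbar + gap)
    rbar = 0.5 * (vessel_radius_px[0] + vessel_radius_px[1])
    gap = 2 * rbar * (1.0 / target_vessel_fraction - 1.0)
    # one shared waviness field keeps the bundle parallel (non-overlapping)
    t = np.linspace(0.0, 1.0, 64)
    ys = t * (ny - 1)
    wave = (rng.uniform(0.04, 0.07) * nx
            * np.sin(2 * np.pi * rng.uniform(0.5, 1.2) * t + rng.uniform(0, 2 * np.pi)))
    tilt = rng.uniform(-0.15, 0.15)
    vessels: list[Vessel] = []
    x = rng.uniform(0.0, gap) + vessel_radius_px[1]
    while x < nx - 1:
        r = rng.uniform(*vessel_radius_px)
        xs = x + tilt * (ys - ny / 2) + wave
        vessels.append(Vessel(path=np.column_stack([xs, ys]), radius_px=r,
                              delta=delta, depth_frac=rng.uniform(0.3, 0.7)))
        x += 2 * r + gap
    spec.vessels = vessels
    return spec


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

def nearest_correlation(r: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Project a symmetric matrix to the nearest valid correlation matrix
    by eigenvalue clipping followed by diagonal renormalisation."""
    r = 0.5 * (r + r.T)
    w, v = np.linalg.eigh(r)
    w = np.clip(w, eps, None)
    r2 = (v * w) @ v.T
    d = np.sqrt(np.diag(r2))
    r2 = r2 / np.outer(d, d)
    np.fill_diagonal(r2, 1.0)
    return r2


# Per-group means and SDs for the simulated covariates; values follow the
# published normal / POAG / NTG group summaries for this cohort design
# (ages in years, pressures in mmHg, RNFL in um, rim area in mm^2, visual
# field indices in dB, perfusion metrics dimensionless in [0, 1]).
_DEFAULT_MOMENTS: dict[str, dict[str, tuple[float, float]]] = {
    "normal": {
        "age": (68.6, 10.4), "iop": (13.5, 3.4),
        "sbp": (134.7, 20.5), "dbp": (80.4, 12.5),
        "rnfl": (90.0, 11.5), "cdr": (0.44, 0.17), "rim_area": (1.28, 0.20),
        "flux": (0.33, 0.04), "vessel_density": (0.77, 0.02),
        "normalized_flux": (0.37, 0.04),
    },
    "POAG": {
        "age": (64.6, 10.9), "iop": (14.8, 4.0),
        "sbp": (125.8, 19.0), "dbp": (78.2, 12.2),
        "vf_md": (-5.49, 6.79), "vf_psd": (5.82, 4.05),
        "rnfl": (64.9, 9.3), "cdr": (0.74, 0.10), "rim_area": (0.76, 0.19),
        "flux": (0.24, 0.07), "vessel_density": (0.68, 0.08),
        "normalized_flux": (0.29, 0.05),
    },
    "NTG": {
        "age": (66.2, 12.2), "iop": (12.0, 3.3),
        "sbp": (132.8, 15.6), "dbp": (74.7, 9.6),
        "vf_md": (-4.79, 5.04), "vf_psd": (6.93, 4.30),
        "rnfl": (71.6, 12.2), "cdr": (0.73, 0.09), "rim_area": (0.80, 0.18),
        "flux": (0.25, 0.06), "vessel_density": (0.70, 0.07),
        "normalized_flux": (0.30, 0.05),
    },
}

# Signed pairwise correlations.  Metric-covariate entries are the square
# roots of the published per-group univariate R^2 values with signs set by
# the clinically reported directions (perfusion decreases with worse MD,
# higher PSD, thinner RNFL, larger cup/disc ratio, smaller rim area).
_METRICS = ("flux", "vessel_density", "normalized_flux")

_METRIC_COVARIATE_R2: dict[str, dict[str, tuple[float, float, float]]] = {
    # variable: (R^2 flux, R^2 density, R^2 normalized flux)
    "POAG": {
        "vf_md": (0.16, 0.09, 0.16), "vf_psd": (0.26, 0.17, 0.23),
        "iop": (0.003, 0.03, 0.0002), "rnfl": (0.42, 0.20, 0.46),
        "cdr": (0.57, 0.33, 0.58), "rim_area": (0.34, 0.19, 0.35),
    },
    "NTG": {
        "vf_md": (0.22, 0.15, 0.20), "vf_psd": (0.19, 0.13, 0.18),
        "iop": (0.13, 0.13, 0.11), "rnfl": (0.03, 0.07, 0.01),
        "cdr": (0.15, 0.22, 0.09), "rim_area": (0.21, 0.28, 0.16),
    },
    "normal": {
        "iop": (0.02, 0.03, 0.02), "rnfl": (0.10, 0.26, 0.08),
        "cdr": (0.10, 0.03, 0.10), "rim_area": (0.08, 0.28, 0.05),
    },
}

_COVARIATE_SIGN = {
    "vf_md": +1.0, "vf_psd": -1.0, "iop": -1.0,
    "rnfl": +1.0, "cdr": -1.0, "rim_area": +1.0,
}

_COVARIATE_PAIRS = {
    ("sbp", "dbp"): 0.60,
    ("vf_md", "vf_psd"): -0.75,
    ("rnfl", "cdr"): -0.55,
    ("rnfl", "rim_area"): 0.55,
    ("cdr", "rim_area"): -0.75,
    ("vf_md", "rnfl"): 0.45,
    ("vf_md", "cdr"): -0.40,
    ("vf_md", "rim_area"): 0.40,
    ("vf_psd", "rnfl"): -0.40,
    ("vf_psd", "cdr"): 0.35,
    ("vf_psd", "rim_area"): -0.35,
}

_METRIC_PAIRS = {
    ("flux", "vessel_density"): 0.75,
    ("flux", "normalized_flux"): 0.85,
    ("vessel_density", "normalized_flux"): 0.55,
}


@dataclass
class CohortSpec:
    """Specification of a simulated three-group cohort.

    ``moments[group][variable] = (mean, sd)``; ``correlations[group]`` is a
    correlation DataFrame over that group's variables.  Matrices supplied by
    the user must be positive semidefinite (checked); the built-in defaults
    are projected to the nearest valid correlation matrix at construction.
    """

    group_sizes: dict[str, int]
    moments: dict[str, dict[str, tuple[float, float]]]
    correlations: dict[str, pd.DataFrame]
    seed: int = 0

    def __post_init__(self) -> None:
        for g, n in self.group_sizes.items():
            if g not in GROUPS:
                raise ValueError(f"unknown group {g!r}; expected one of {GROUPS}")
            if n < 2:
                raise ValueError(f"group {g!r} needs at least 2 eyes, got {n}")
        for g in self.group_sizes:
            for var, (m, s) in self.moments[g].items():
                if not s > 0:
                    raise ValueError(f"SD for {g}/{var} must be > 0, got {s}")
            corr = self.correlations[g]
            if list(corr.index) != list(corr.columns):
                raise ValueError("correlation matrix index/columns must match")
            w = np.linalg.eigvalsh(0.5 * (corr.values + corr.values.T))
            if w.min() < -1e-8:
                raise ValueError(
                    f"correlation matrix for group {g!r} is not positive semidefinite"
                )

    def variables(self, group: str) -> list[str]:
        return list(self.correlations[group].columns)


def default_cohort_spec(
    group_sizes: dict[str, int] | None = None, seed: int = 0
) -> CohortSpec:
    """Default cohort: published group moments and signed-sqrt(R^2)
    correlations, one matrix per group, projected to valid correlations."""
    group_sizes = dict(group_sizes or {"normal": 28, "POAG": 30, "NTG": 31})
    correlations = {}
    for g in group_sizes:
        varnames = list(_DEFAULT_MOMENTS[g])
        k = len(varnames)
        r = np.eye(k)
        idx = {v: i for i, v in enumerate(varnames)}

        def put(a: str, b: str, val: float) -> None:
            if a in idx and b in idx:
                r[idx[a], idx[b]] = r[idx[b], idx[a]] = val

        for var, r2s in _METRIC_COVARIATE_R2[g].items():
            for metric, r2 in zip(_METRICS, r2s):
                put(metric, var, _COVARIATE_SIGN[var] * np.sqrt(r2))
        for (a, b), val in _COVARIATE_PAIRS.items():
            put(a, b, val)
        for (a, b), val in _METRIC_PAIRS.items():
            put(a, b, val)
        r = nearest_correlation(r)
        correlations[g] = pd.DataFrame(r, index=varnames, columns=varnames)
    moments = {g: dict(_DEFAULT_MOMENTS[g]) for g in group_sizes}
    return CohortSpec(group_sizes=group_sizes, moments=moments,
                      correlations=correlations, seed=seed)


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw the per-eye cohort table from the group-specific Gaussians.

    Returns one row per eye with an ``eye_id``, ``group`` label, the
    simulated covariates and perfusion metrics, computed ``mopp``, and QC
    fields (``signal_strength`` in [0, 10], ``motion_flag``).  Perfusion
    metrics are clipped to [0, 1] and SBP is kept >= DBP (physiological
    pulse pressure floor of 5 mmHg).
    """
    rng = np.random.default_rng(spec.seed)
    frames = []
    for g in GROUPS:
        if g not in spec.group_sizes:
            continue
        n = spec.group_sizes[g]
        varnames = spec.variables(g)
        mean = np.array([spec.moments[g][v][0] for v in varnames])
        sd = np.array([spec.moments[g][v][1] for v in varnames])
        corr = spec.correlations[g].values
        cov = corr * np.outer(sd, sd)
        draws = rng.multivariate_normal(mean, cov, size=n, method="svd")
        df = pd.DataFrame(draws, columns=varnames)
        df.insert(0, "group", g)
        frames.append(df)
    table = pd.concat(frames, ignore_index=True)
    for m in _METRICS:
        table[m] = table[m].clip(0.0, 1.0)
    table["cdr"] = table["cdr"].clip(0.0, 1.0)
    table["sbp"] = np.maximum(table["sbp"], table["dbp"] + 5.0)
    table["iop"] = table["iop"].clip(1.0, None)
    table["mopp"] = compute_mopp(table["sbp"], table["dbp"], table["iop"])
    table["signal_strength"] = np.clip(
        np.round(rng.normal(8.0, 1.0, size=len(table))), 0, 10
    ).astype(int)
    table["motion_flag"] = False
    table.insert(0, "eye_id", [f"eye{i:04d}" for i in range(len(table))])
    return table


def cohort_column_dictionary() -> dict[str, str]:
    """Column dictionary for cohort CSVs (units and meaning)."""
    return {
        "eye_id": "unique per-eye identifier",
        "group": "diagnosis group: normal, POAG or NTG",
        "age": "age in years",
        "iop": "intraocular pressure, mmHg",
        "sbp": "systolic blood pressure, mmHg",
        "dbp": "diastolic blood pressure, mmHg",
        "mopp": "mean ocular perfusion pressure = 2/3(MAP - IOP), mmHg",
        "vf_md": "visual field mean deviation, dB (glaucoma groups only)",
        "vf_psd": "visual field pattern standard deviation, dB",
        "rnfl": "global average RNFL thickness, um",
        "cdr": "averaged cup-to-disc ratio",
        "rim_area": "neuroretinal rim area, mm^2",
        "flux": "mean normalized flow over the disc, dimensionless [0, 1]",
        "vessel_density": "vessel area fraction inside the disc [0, 1]",
        "normalized_flux": "mean normalized flow over vessel pixels [0, 1]",
        "signal_strength": "device scan quality index 0-10 (exclude < 6)",
        "motion_flag": "True if noticeable eye movement was seen",
    }
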