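"""Scalable-MC record reweighting, fiber-geometry collection, the
reflectance lookup table used by the inversion, and the inter-channel
crosstalk simulation."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RectBivariateSpline

from ..optics import OpticalProperties
from .simulate import (
    BaselineSimulation,
    ChannelGeometry,
    LayeredMedium,
    run_mc,
)

#: validated similarity-scaling envelope: printed phantom range +/- 50%
VALID_MUSP_RANGE = (3.5, 14.6)
VALID_MUA_RANGE = (0.0, 13.3)

#: radial resolution of the collection kernel (10 um bins out to 2 cm)
KERNEL_R_STEP_CM = 0.001
KERNEL_R_MAX_CM = 2.0


def _arc_fraction(r, d, a):
    """Fraction of a circle of radius ``r`` centred a distance ``d`` from a
    disc of radius ``a`` that lies inside the disc.  Vectorized in r, d."""
    r = np.asarray(r, dtype=float)
    d = np.asarray(d, dtype=float)
    out = np.zeros(np.broadcast_shapes(r.shape, d.shape))
    r, d = np.broadcast_arrays(r, d)
    inside = r + d <= a
    out[inside] = 1.0
    partial = (~inside) & (np.abs(d - a) < r) & (r < d + a)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosval = (d[partial] ** 2 + r[partial] ** 2 - a**2) / (2.0 * d[partial] * r[partial])
    out[partial] = np.arccos(np.clip(cosval, -1.0, 1.0)) / np.pi
    # r == 0 degenerates to a point test
    zero = r <= 1e-15
    out[zero] = (d[zero] <= a).astype(float)
    return out


def collection_kernel(
    r_grid: np.ndarray,
    d_cm: float,
    src_radius_cm: float,
    det_radius_cm: float,
    n_quad: int = 16,
) -> np.ndarray:
    """Probability that a photon exiting at radius ``r`` from a launch point
    drawn uniformly over the source-fiber face (uniform azimuth) lands on
    the detector-fiber face a distance ``d_cm`` away."""
    # area-uniform polar quadrature over the source disc
    u, wu = np.polynomial.legendre.leggauss(n_quad)
    u = 0.5 * (u + 1.0)
    wu = 0.5 * wu
    rho = np.sqrt(u) * src_radius_cm
    theta = 2.0 * np.pi * (np.arange(n_quad) + 0.5) / n_quad
    qx = d_cm - rho[:, None] * np.cos(theta)[None, :]
    qy = rho[:, None] * np.sin(theta)[None, :]
    dist = np.hypot(qx, qy).ravel()
    wgt = np.repeat(wu / n_quad, n_quad)
    frac = _arc_fraction(r_grid[:, None], dist[None, :], det_radius_cm)
    return frac @ wgt


@dataclass
class ScaledRecords:
    """Baseline exit records reweighted to target optical properties."""

    exit_radius: np.ndarray
    exit_cosine: np.ndarray
    weight: np.ndarray
    photon_count: int
    mu_s: float
    mu_a: float
    g: float


def scale_to_target(
    baseline: BaselineSimulation,
    target: OpticalProperties,
    wavelength_index: int = 0,
) -> ScaledRecords:
    """Similarity-scale a zero-absorption baseline to target properties.

    Exit radii and path lengths scale with the ratio of interaction
    coefficients; absorption enters as ``exp(-mu_a * path)``.
    """
    if baseline.mu_a.size != 1:
        raise ValueError("scaling requires a single-layer baseline")
    if baseline.mu_a[0] != 0.0:
        raise ValueError("scaling requires a zero-absorption baseline")
    j = min(wavelength_index, target.mu_a.size - 1)
    mu_a = float(target.mu_a[j])
    musp = float(target.mu_s_prime[j])
    g = float(target.g[j])
    if mu_a < 0:
        raise ValueError("target mu_a must be non-negative")
    if abs(g - baseline.g[0]) > 1e-9:
        raise ValueError("target anisotropy must match the baseline")
    if not (VALID_MUSP_RANGE[0] <= musp <= VALID_MUSP_RANGE[1]) or not (
        VALID_MUA_RANGE[0] <= mu_a <= VALID_MUA_RANGE[1]
    ):
        warnings.warn(
            f"target (mu_s'={musp:.2f}, mu_a={mu_a:.2f}) outside validated "
            f"scaling range; prefer a direct simulation",
            stacklevel=2,
        )
    mu_s = musp / (1.0 - g)
    f = baseline.mu_s[0] / mu_s
    path = baseline.total_path * f
    return ScaledRecords(
        exit_radius=baseline.exit_radius * f,
        exit_cosine=baseline.exit_cosine,
        weight=baseline.weight * np.exp(-mu_a * path),
        photon_count=baseline.photon_count,
        mu_s=mu_s,
        mu_a=mu_a,
        g=g,
    )


def _na_accept(exit_cosine: np.ndarray, geometry: ChannelGeometry) -> np.ndarray:
    """Acceptance mask: exit direction within the fiber NA, evaluated in air."""
    sin_air = np.sqrt(np.clip(1.0 - exit_cosine**2, 0.0, 1.0))
    return sin_air <= min(geometry.numerical_aperture, 1.0)


def channel_reflectance(
    records,
    geometry: ChannelGeometry,
    det_radius_cm: float | None = None,
) -> float:
    """Per-channel reflectance: exiting weight integrated over the detector
    face, averaged over the 8 ring source fibers (identical by symmetry),
    per unit launched photon weight."""
    if records.exit_radius.size == 0:
        raise ValueError("empty record set")
    a_det = geometry.fiber_radius_cm if det_radius_cm is None else det_radius_cm
    keep = _na_accept(records.exit_cosine, geometry)
    r = records.exit_radius[keep]
    w = records.weight[keep]
    if a_det >= KERNEL_R_MAX_CM:
        # infinite-detector completeness limit
        return float(w.sum() / records.photon_count)
    r_grid = np.arange(0.0, KERNEL_R_MAX_CM + KERNEL_R_STEP_CM, KERNEL_R_STEP_CM)
    kern = collection_kernel(r_grid, geometry.sds_cm, geometry.fiber_radius_cm, a_det)
    k = np.interp(r, r_grid, kern, right=0.0)
    return float((w * k).sum() / records.photon_count)


def channel_reflectance_explicit(
    records,
    geometry: ChannelGeometry,
    rng: np.random.Generator,
) -> np.ndarray:
    """Direct-geometry collection oracle: sample explicit launch points on
    each of the 8 source-fiber faces and test exit points against the
    detector disc (no radial convolution kernel).  Returns the per-fiber
    reflectance estimates."""
    if records.exit_radius.size == 0:
        raise ValueError("empty record set")
    keep = _na_accept(records.exit_cosine, geometry)
    r = records.exit_radius[keep]
    w = records.weight[keep]
    a = geometry.fiber_radius_cm
    d = geometry.sds_cm
    out = np.empty(geometry.n_illumination_fibers)
    for k in range(geometry.n_illumination_fibers):
        # launch point uniform on the fiber face; detector at the ring centre
        rho = a * np.sqrt(rng.random(r.size))
        ang = 2 * np.pi * rng.random(r.size)
        phi = 2 * np.pi * rng.random(r.size)
        px = d + rho * np.cos(ang) + r * np.cos(phi)
        py = rho * np.sin(ang) + r * np.sin(phi)
        hit = px * px + py * py <= a * a
        out[k] = (w * hit).sum() / records.photon_count
    return out


class ReflectanceLUT:
    """Channel reflectance R(mu_s', mu_a) interpolated from one scaled
    baseline; the forward model behind the spectral fits."""

    def __init__(
        self,
        baseline: BaselineSimulation,
        geometry: ChannelGeometry | None = None,
        musp_grid: np.ndarray | None = None,
        mua_grid: np.ndarray | None = None,
    ):
        geometry = geometry or ChannelGeometry()
        if musp_grid is None:
            musp_grid = np.linspace(2.0, 16.0, 36)
        if mua_grid is None:
            mua_grid = np.concatenate([[0.0], np.geomspace(0.05, 16.0, 39)])
        self.geometry = geometry
        self.g = float(baseline.g[0])
        self.musp_grid = np.asarray(musp_grid, dtype=float)
        self.mua_grid = np.asarray(mua_grid, dtype=float)

        keep = _na_accept(baseline.exit_cosine, geometry)
        r0 = baseline.exit_radius[keep]
        w0 = baseline.weight[keep]
        l0 = baseline.total_path[keep]
        mu_s_b = baseline.mu_s[0]
        n_ph = baseline.photon_count

        r_grid = np.arange(0.0, KERNEL_R_MAX_CM + KERNEL_R_STEP_CM, KERNEL_R_STEP_CM)
        kern = collection_kernel(
            r_grid, geometry.sds_cm, geometry.fiber_radius_cm, geometry.fiber_radius_cm
        )
        table = np.empty((self.musp_grid.size, self.mua_grid.size))
        for i, musp in enumerate(self.musp_grid):
            f = mu_s_b / (musp / (1.0 - self.g))
            k = np.interp(r0 * f, r_grid, kern, right=0.0)
            nz = k > 0
            base = w0[nz] * k[nz]
            path = l0[nz] * f
            table[i] = (base[:, None] * np.exp(-path[:, None] * self.mua_grid[None, :])).sum(
                axis=0
            ) / n_ph
        self.table = table
        self._spline = RectBivariateSpline(self.musp_grid, self.mua_grid, table, kx=3, ky=3)

    def __call__(self, musp, mua) -> np.ndarray:
        musp = np.clip(np.asarray(musp, dtype=float), self.musp_grid[0], self.musp_grid[-1])
        mua = np.clip(np.asarray(mua, dtype=float), self.mua_grid[0], self.mua_grid[-1])
        musp, mua = np.broadcast_arrays(musp, mua)
        out = self._spline.ev(musp.ravel(), mua.ravel()).reshape(musp.shape)
        return np.clip(out, 0.0, None)


@dataclass
class CrosstalkResult:
    percent: float
    stderr: float
    collected_own: float
    collected_neighbors: float


def _fiber_distances(pitch_cm: float, geometry: ChannelGeometry):
    """Centre-to-centre distances from the central detection fiber to every
    illumination fiber of the centre channel and of its 8 neighbours."""
    ring = geometry.sds_cm
    ang = 2 * np.pi * np.arange(geometry.n_illumination_fibers) / geometry.n_illumination_fibers
    fib = np.stack([ring * np.cos(ang), ring * np.sin(ang)], axis=1)
    own = np.hypot(fib[:, 0], fib[:, 1])
    centers = np.array(
        [(dx, dy) for dx in (-1, 0, 1) for dy in (-1, 0, 1) if (dx, dy) != (0, 0)],
        dtype=float,
    ) * pitch_cm
    neigh = np.hypot(
        centers[:, None, 0] + fib[None, :, 0], centers[:, None, 1] + fib[None, :, 1]
    ).ravel()
    return own, neigh


def crosstalk_fraction(
    props: OpticalProperties,
    pitch_mm: float,
    geometry: ChannelGeometry | None = None,
    n_photons: int = 2_000_000,
    seed: int = 1,
    records=None,
    n_batches: int = 20,
) -> CrosstalkResult:
    """Centre-pixel crosstalk: the percentage of weight collected by the
    central detection fiber that originated from the illumination fibers of
    the 8 neighbouring channels at the given pitch.

    A precomputed record set (direct run or scaled baseline) may be passed
    via ``records`` to evaluate several pitches from one simulation.
    """
    if pitch_mm <= 0:
        raise ValueError("pitch must be positive")
    geometry = geometry or ChannelGeometry()
    if records is None:
        medium = LayeredMedium.semi_infinite(props)
        records = run_mc(medium, n_photons, seed)
    keep = _na_accept(records.exit_cosine, geometry)
    r = records.exit_radius[keep]
    w = records.weight[keep]

    own_d, neigh_d = _fiber_distances(pitch_mm / 10.0, geometry)
    r_grid = np.arange(0.0, KERNEL_R_MAX_CM + KERNEL_R_STEP_CM, KERNEL_R_STEP_CM)
    a = geometry.fiber_radius_cm

    def collected(dists):
        tot = np.zeros(r.size)
        for d in dists:
            kern = collection_kernel(r_grid, d, a, a)
            tot += np.interp(r, r_grid, kern, right=0.0)
        return tot * w

    per_rec_own = collected(own_d)
    per_rec_neigh = collected(neigh_d)
    own = float(per_rec_own.sum())
    neigh = float(per_rec_neigh.sum())
    if own + neigh <= 0:
        raise ValueError("no collected weight; increase photon count")
    percent = 100.0 * neigh / (own + neigh)

    # batch-means standard error over independent photon blocks
    edges = np.linspace(0, r.size, n_batches + 1, dtype=int)
    vals = []
    for b in range(n_batches):
        s = slice(edges[b], edges[b + 1])
        o, nb = per_rec_own[s].sum(), per_rec_neigh[s].sum()
        if o + nb > 0:
            vals.append(100.0 * nb / (o + nb))
    vals = np.asarray(vals)
    stderr = float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else float("nan")
    return CrosstalkResult(percent, stderr, own, neigh)
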