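"""Fixture generators: the 12-phantom dilution series, synthetic breast
margins with class-dependent optical parameters, and raw-frame synthesis
with the instrument noise model.

Tissue-class parameter defaults are package inventions chosen to honour
two external constraints: the adipose band averages used in the crosstalk
simulation (<mu_s'> = 6.9 cm^-1, <mu_a> = 4.6 cm^-1) and the qualitative
ordering of the [beta-carotene]/<mu_s'> ratio from adipose down to
fibroglandular tissue.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .landscape import DensityStratum
from .optics import (
    DEFAULT_BAND,
    G_TISSUE_DEFAULT,
    LN10,
    N_WATER,
    AbsorberSpectrum,
    OpticalProperties,
    SphereScattererSpec,
    WavelengthGrid,
    band_average,
    load_default_absorbers,
    mie_reduced_scattering,
)
from .scan import Frame, ProbeArray, RasterPlan

# ---------------------------------------------------------------------------
# phantom dilution series (printed table transcription)
# ---------------------------------------------------------------------------

_TABLE1 = (
    # (id, <mu_s'> cm^-1, <mu_a> cm^-1, [Hb] uM)
    (1, 9.73, 0.0, 0.0),
    (2, 9.41, 1.07, 13.89),
    (3, 9.12, 2.07, 26.87),
    (4, 8.84, 3.01, 39.07),
    (5, 8.58, 3.90, 50.62),
    (6, 8.34, 4.70, 61.00),
    (7, 8.10, 5.50, 71.39),
    (8, 7.89, 6.25, 81.12),
    (9, 7.68, 6.96, 90.34),
    (10, 7.48, 7.63, 99.04),
    (11, 7.29, 8.26, 107.22),
    (12, 7.03, 8.86, 115.01),
)


@dataclass(frozen=True)
class PhantomSpec:
    phantom_id: int
    musp_expected: float  # band-averaged <mu_s'>, cm^-1
    mua_expected: float  # band-averaged <mu_a>, cm^-1
    hb_uM: float


def table1_phantoms() -> list[PhantomSpec]:
    """The 12-phantom reference set (band averages over 450-600 nm)."""
    return [PhantomSpec(*row) for row in _TABLE1]


def hb_band_coefficient() -> float:
    """Band-averaged absorption per unit hemoglobin concentration implied
    by the phantom table (cm^-1 per uM); constant across the dilution
    series to <0.1%."""
    rows = [r for r in _TABLE1 if r[3] > 0]
    return float(np.mean([mua / hb for _, _, mua, hb in rows]))


class PhantomOpticalModel:
    """Maps a PhantomSpec to full optical-property spectra.

    The hemoglobin extinction shape comes from the bundled compilation,
    rescaled so that its band-averaged absorption per uM matches the
    phantom table exactly (the table is ground truth for phantoms).  The
    scattering shape comes from Mie theory for 1 um polystyrene spheres in
    water, with the sphere density calibrated so phantom 1 band-averages
    to 9.73 cm^-1; the dilution factor of each subsequent phantom is the
    ratio of its printed band average to phantom 1's.
    """

    def __init__(
        self,
        grid: WavelengthGrid | None = None,
        absorbers: dict[str, AbsorberSpectrum] | None = None,
        g_transport: float = G_TISSUE_DEFAULT,
    ):
        self.grid = grid or WavelengthGrid.analysis_band()
        self.absorbers = absorbers or load_default_absorbers()
        self.g_transport = g_transport

        eps = self.absorbers["hemoglobin"].on_grid(self.grid)
        per_uM = LN10 * eps * 1e-6  # mu_a per uM, unscaled
        self._hb_shape = per_uM * (hb_band_coefficient() / band_average(per_uM, self.grid))

        unit_spec = SphereScattererSpec(1.0, number_density_per_ml=1.0)
        musp_unit, g_mie = mie_reduced_scattering(unit_spec, self.grid)
        self.mie_g = g_mie
        ref = table1_phantoms()[0]
        self._density_ref = ref.musp_expected / band_average(musp_unit, self.grid)
        self._musp_ref = musp_unit * self._density_ref  # phantom 1 spectrum

    def sphere_density(self, spec: PhantomSpec) -> float:
        """Spheres/mL after the dilution implied by the printed column."""
        ref = table1_phantoms()[0]
        return self._density_ref * spec.musp_expected / ref.musp_expected

    def mu_a(self, hb_uM: float) -> np.ndarray:
        return self._hb_shape * hb_uM

    def mu_s_prime(self, spec: PhantomSpec) -> np.ndarray:
        ref = table1_phantoms()[0]
        return self._musp_ref * (spec.musp_expected / ref.musp_expected)

    def optical_properties(self, spec: PhantomSpec) -> OpticalProperties:
        """Spectra for transport; anisotropy is the fixed transport value
        (reduced-scattering similarity), with the Mie anisotropy kept as
        metadata in ``self.mie_g``."""
        return OpticalProperties(
            mu_a=self.mu_a(spec.hb_uM),
            mu_s_prime=self.mu_s_prime(spec),
            g=np.full(len(self.grid), self.g_transport),
            n_medium=N_WATER,
        )


# ---------------------------------------------------------------------------
# tissue classes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TissueClassModel:
    """Generator parameters for one tissue class (package inventions)."""

    label: str
    bcar_uM: float  # mean beta-carotene concentration
    hb_uM: float  # mean hemoglobin concentration
    musp_band: float  # mean band-averaged reduced scattering, cm^-1
    scatter_power: float  # mu_s'(lambda) ~ (lambda/550)^-b exponent
    rel_sd: float = 0.12  # lognormal relative spread of bcar and musp
    correlation_length_mm: float = 2.0

    @property
    def ratio(self) -> float:
        return self.bcar_uM / self.musp_band


#: class code 0 is reserved for off-margin background
TISSUE_CLASSES: dict[str, TissueClassModel] = {
    "adipose": TissueClassModel("adipose", bcar_uM=18.0, hb_uM=38.0, musp_band=6.9,
                                scatter_power=0.6),
    "fat_fibroglandular": TissueClassModel("fat_fibroglandular", bcar_uM=12.0, hb_uM=42.0,
                                           musp_band=8.5, scatter_power=0.9),
    "fibroadipose": TissueClassModel("fibroadipose", bcar_uM=8.0, hb_uM=45.0,
                                     musp_band=9.5, scatter_power=1.1),
    "fibroglandular": TissueClassModel("fibroglandular", bcar_uM=5.0, hb_uM=50.0,
                                       musp_band=11.5, scatter_power=1.3),
    "dcis": TissueClassModel("dcis", bcar_uM=3.0, hb_uM=60.0, musp_band=13.0,
                             scatter_power=1.4),
}

CLASS_CODES = {name: i + 1 for i, name in enumerate(TISSUE_CLASSES)}
CODE_NAMES = {v: k for k, v in CLASS_CODES.items()}


def _shape_factor(b: np.ndarray, grid: WavelengthGrid) -> np.ndarray:
    """Band average of (lambda/550)^-b, so musp_band = a * factor."""
    lam = grid.values[grid.band_mask(DEFAULT_BAND)] / 550.0
    b = np.atleast_1d(np.asarray(b, dtype=float))
    return np.mean(lam[None, :] ** (-b[:, None]), axis=1)


@dataclass(frozen=True)
class LesionSpec:
    """A focal class patch (disc) inserted inside the margin."""

    diameter_mm: float
    tissue_class: str = "dcis"
    center_mm: tuple[float, float] | None = None  # defaults to margin centre

    def __post_init__(self):
        if self.diameter_mm <= 0:
            raise ValueError("lesion diameter must be positive")
        if self.tissue_class not in TISSUE_CLASSES:
            raise ValueError(f"unknown tissue class {self.tissue_class!r}")


@dataclass
class SyntheticMargin:
    """Ground-truth tissue map on a fine grid."""

    class_map: np.ndarray  # int codes, 0 = background
    bcar: np.ndarray  # uM
    hb: np.ndarray  # uM
    musp_band: np.ndarray  # band-averaged mu_s', cm^-1
    scatter_power: np.ndarray
    boundary_mask: np.ndarray
    pixel_mm: float
    stratum: str
    seed: int
    lesion: LesionSpec | None = None

    @property
    def extent_mm(self) -> float:
        return self.class_map.shape[0] * self.pixel_mm

    @property
    def ratio_true(self) -> np.ndarray:
        out = np.full(self.bcar.shape, np.nan)
        m = self.boundary_mask
        out[m] = self.bcar[m] / self.musp_band[m]
        return out


#: default fibroglandular-area fractions per stratum
FIBRO_FRACTION = {"LBD": 0.20, "HBD": 0.55}


def _grf(shape, sigma_px, rng) -> np.ndarray:
    """Unit-variance Gaussian random field with correlation scale sigma."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma_px, mode="wrap")
    return (f - f.mean()) / f.std()


def generate_margin(
    stratum: DensityStratum | str,
    lesion: LesionSpec | None = None,
    seed: int = 0,
    extent_mm: float = 42.0,
    pixel_mm: float = 0.25,
    fibro_fraction: float | None = None,
) -> SyntheticMargin:
    """Gaussian-random-field class texture inside an elliptical margin.

    HBD margins default to a higher fibroglandular area fraction than LBD
    (0.55 vs 0.20).  Deterministic for a fixed seed.
    """
    label = stratum.label if isinstance(stratum, DensityStratum) else str(stratum)
    if label not in FIBRO_FRACTION:
        raise ValueError("stratum must be LBD or HBD")
    frac = FIBRO_FRACTION[label] if fibro_fraction is None else float(fibro_fraction)
    if not 0.0 <= frac <= 0.9:
        raise ValueError("fibroglandular fraction out of range")

    rng = np.random.default_rng(seed)
    npx = int(round(extent_mm / pixel_mm))
    shape = (npx, npx)
    sigma = TISSUE_CLASSES["adipose"].correlation_length_mm / pixel_mm

    # elliptical margin boundary
    yy, xx = np.mgrid[0:npx, 0:npx]
    cy, cx = (npx - 1) / 2, (npx - 1) / 2
    ay = 0.46 * npx * (1 + 0.05 * rng.standard_normal())
    ax = 0.46 * npx * (1 + 0.05 * rng.standard_normal())
    boundary = ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0

    # composition texture: one field drives the class partition
    comp = _grf(shape, sigma, rng)
    inside = comp[boundary]
    q_fg = np.quantile(inside, 1.0 - frac)
    q_fa = np.quantile(inside, max(0.0, 1.0 - frac - 0.10))
    q_mix = np.quantile(inside, max(0.0, 1.0 - frac - 0.30))
    class_map = np.zeros(shape, dtype=np.int8)
    class_map[boundary] = CLASS_CODES["adipose"]
    class_map[boundary & (comp > q_mix)] = CLASS_CODES["fat_fibroglandular"]
    class_map[boundary & (comp > q_fa)] = CLASS_CODES["fibroadipose"]
    class_map[boundary & (comp > q_fg)] = CLASS_CODES["fibroglandular"]

    if lesion is not None:
        if lesion.diameter_mm >= extent_mm:
            raise ValueError("lesion larger than margin")
        if lesion.center_mm is None:
            lc = (cy * pixel_mm, cx * pixel_mm)
        else:
            lc = lesion.center_mm
        rr = ((yy - lc[0] / pixel_mm) ** 2 + (xx - lc[1] / pixel_mm) ** 2) <= (
            lesion.diameter_mm / 2 / pixel_mm
        ) ** 2
        if not np.all(boundary[rr]):
            raise ValueError("lesion not fully inside the margin boundary")
        class_map[rr] = CLASS_CODES[lesion.tissue_class]

    # per-pixel parameters: class mean with spatially correlated lognormal
    # jitter (mean-preserving)
    bcar = np.zeros(shape)
    hb = np.zeros(shape)
    musp = np.zeros(shape)
    bpow = np.zeros(shape)
    jit_b = _grf(shape, sigma, rng)
    jit_s = _grf(shape, sigma, rng)
    for name, model in TISSUE_CLASSES.items():
        sel = class_map == CLASS_CODES[name]
        if not sel.any():
            continue
        s = model.rel_sd
        bcar[sel] = model.bcar_uM * np.exp(s * jit_b[sel] - s * s / 2)
        musp[sel] = model.musp_band * np.exp(s * jit_s[sel] - s * s / 2)
        hb[sel] = model.hb_uM
        bpow[sel] = model.scatter_power
    return SyntheticMargin(
        class_map=class_map,
        bcar=bcar,
        hb=hb,
        musp_band=musp,
        scatter_power=bpow,
        boundary_mask=boundary,
        pixel_mm=pixel_mm,
        stratum=label,
        seed=seed,
        lesion=lesion,
    )


# ---------------------------------------------------------------------------
# instrument / frame synthesis
# ---------------------------------------------------------------------------


def lamp_spectrum(grid: WavelengthGrid) -> np.ndarray:
    """Smooth source spectral shape: two white emitters plus cyan and blue
    peaks approximating flat output from 420-600 nm, normalized to peak 1."""
    lam = grid.values
    out = (
        1.0 * np.exp(-0.5 * ((lam - 470) / 12.0) ** 2)
        + 0.9 * np.exp(-0.5 * ((lam - 510) / 15.0) ** 2)
        + 0.8 * np.exp(-0.5 * ((lam - 555) / 40.0) ** 2)
        + 0.35 * np.exp(-0.5 * ((lam - 620) / 60.0) ** 2)
    )
    return out / out.max()


@dataclass(frozen=True)
class NoiseModel:
    """Per-snapshot source drift plus shot-like counting noise."""

    drift_sd: float = 0.009  # relative intensity drift per snapshot, <= 2% max
    gain_counts: float = 30_000.0  # counts at a typical tissue signal
    shot_noise: bool = True
    background_level: float = 1e-4  # off-margin channel floor, relative

    def __post_init__(self):
        if not 0 <= self.drift_sd <= 0.02:
            raise ValueError("drift sd must lie in [0, 0.02] (<=2% source variation)")


@dataclass
class RenderedScan:
    frames: list[Frame]
    plan: RasterPlan
    grid: WavelengthGrid
    reference_signal: float  # counts scale mapping reflectance -> counts
    noise: NoiseModel
    seed: int


def _true_params_at(margin: SyntheticMargin, x_mm: np.ndarray, y_mm: np.ndarray,
                    window_mm: float = 0.75):
    """Footprint-averaged true parameters around each (x, y) position.

    Positions outside the margin boundary return background (None flag)."""
    half = max(1, int(round(window_mm / margin.pixel_mm / 2)))
    npx = margin.class_map.shape[0]
    out = np.zeros((x_mm.size, 4))
    on_tissue = np.zeros(x_mm.size, dtype=bool)
    for k, (x, y) in enumerate(zip(x_mm, y_mm)):
        i = int(round(y / margin.pixel_mm))
        j = int(round(x / margin.pixel_mm))
        sl = (slice(max(0, i - half), min(npx, i + half + 1)),
              slice(max(0, j - half), min(npx, j + half + 1)))
        m = margin.boundary_mask[sl]
        if m.mean() < 0.5:
            continue
        on_tissue[k] = True
        out[k, 0] = margin.hb[sl][m].mean()
        out[k, 1] = margin.bcar[sl][m].mean()
        out[k, 2] = margin.musp_band[sl][m].mean()
        out[k, 3] = margin.scatter_power[sl][m].mean()
    return out, on_tissue


class TissueForward:
    """Vectorized tissue reflectance through a (mu_s', mu_a) lookup table."""

    def __init__(self, lut, grid: WavelengthGrid, absorbers=None):
        self.lut = lut
        self.grid = grid
        absorbers = absorbers or load_default_absorbers()
        self.eps_hb = absorbers["hemoglobin"].on_grid(grid)
        self.eps_bc = absorbers["beta_carotene"].on_grid(grid)
        self._shape_cache: dict[float, np.ndarray] = {}

    def musp_spectrum(self, musp_band, b):
        lam = self.grid.values / 550.0
        b = np.atleast_1d(np.asarray(b, dtype=float))
        shape = lam[None, :] ** (-b[:, None])
        factor = _shape_factor(b, self.grid)
        a = np.atleast_1d(np.asarray(musp_band, dtype=float)) / factor
        return a[:, None] * shape

    def mua_spectrum(self, hb_uM, bcar_uM):
        hb = np.atleast_1d(np.asarray(hb_uM, dtype=float))
        bc = np.atleast_1d(np.asarray(bcar_uM, dtype=float))
        return LN10 * 1e-6 * (hb[:, None] * self.eps_hb[None, :]
                              + bc[:, None] * self.eps_bc[None, :])

    def reflectance(self, hb_uM, bcar_uM, musp_band, b) -> np.ndarray:
        """(n_samples, n_wavelengths) model reflectance."""
        musp = self.musp_spectrum(musp_band, b)
        mua = self.mua_spectrum(hb_uM, bcar_uM)
        return self.lut(musp, mua)


def render_frames(
    margin: SyntheticMargin,
    plan: RasterPlan,
    forward: TissueForward,
    noise: NoiseModel | None = None,
    seed: int = 0,
    array: ProbeArray | None = None,
) -> RenderedScan:
    """Synthesize raw frames (49 channels + 2 self-calibration) for a full
    raster scan of ``margin``.

    Per channel: model reflectance at the footprint-averaged local truth,
    times the lamp shape, times a per-snapshot drift factor shared with the
    matching self-calibration channel, plus shot noise.
    """
    noise = noise or NoiseModel()
    array = array or ProbeArray()
    if plan.pitch_mm != array.pitch_mm:
        raise ValueError("plan and probe pitch disagree")
    if array.span_mm > margin.extent_mm + 1e-9:
        raise ValueError("probe footprint exceeds margin extent")
    rng = np.random.default_rng(seed)
    grid = forward.grid
    lamp = lamp_spectrum(grid)
    centers = array.channel_centers_mm()
    parity_odd = (np.indices((7, 7)).sum(axis=0) % 2 == 0).ravel()

    # counts gain referenced to a typical adipose signal
    r_typ = float(forward.reflectance(40.0, 12.0, 8.5, 0.9).mean())
    gain = noise.gain_counts / r_typ

    frames = []
    for (i, j) in plan.offset_indices():
        dx = (i + 0.5) * plan.step_mm - plan.pitch_mm / 2
        dy = (j + 0.5) * plan.step_mm - plan.pitch_mm / 2
        x = centers[..., 0].ravel() + dx
        y = centers[..., 1].ravel() + dy
        params, on_tissue = _true_params_at(margin, x, y)
        refl = np.full((49, len(grid)), noise.background_level * r_typ)
        if on_tissue.any():
            p = params[on_tissue]
            refl[on_tissue] = forward.reflectance(p[:, 0], p[:, 1], p[:, 2], p[:, 3])
        drift_odd = 1.0 + noise.drift_sd * float(rng.standard_normal())
        drift_even = 1.0 + noise.drift_sd * float(rng.standard_normal())
        drift = np.where(parity_odd[:, None], drift_odd, drift_even)
        counts = refl * lamp[None, :] * drift * gain
        if noise.shot_noise:
            counts = counts + rng.standard_normal(counts.shape) * np.sqrt(
                np.clip(counts, 0, None)
            )
        sc_odd = lamp * drift_odd * gain * r_typ
        sc_even = lamp * drift_even * gain * r_typ
        if noise.shot_noise:
            sc_odd = sc_odd + rng.standard_normal(sc_odd.shape) * np.sqrt(sc_odd)
            sc_even = sc_even + rng.standard_normal(sc_even.shape) * np.sqrt(sc_even)
        frames.append(
            Frame(
                spectra=counts,
                sc_odd=sc_odd,
                sc_even=sc_even,
                offset_index=(i, j),
                offset_mm=(i * plan.step_mm, j * plan.step_mm),
                metadata={"on_tissue": on_tissue.reshape(7, 7)},
            )
        )
    return RenderedScan(frames, plan, grid, gain, noise, seed)


def render_reference(
    forward: TissueForward,
    hb_uM: float = 40.0,
    bcar_uM: float = 12.0,
    musp_band: float = 8.5,
    scatter_power: float = 0.9,
    noise: NoiseModel | None = None,
    seed: int = 100,
) -> dict:
    """A reference measurement with known optical properties, rendered with
    the same instrument model as :func:`render_frames`.

    Returns ``{"raw", "sc", "model"}``: the raw counts spectrum, its
    self-calibration spectrum, and the known model reflectance.
    """
    noise = noise or NoiseModel()
    rng = np.random.default_rng(seed)
    grid = forward.grid
    lamp = lamp_spectrum(grid)
    model = forward.reflectance(hb_uM, bcar_uM, musp_band, scatter_power)[0]
    r_typ = float(forward.reflectance(40.0, 12.0, 8.5, 0.9).mean())
    gain = noise.gain_counts / r_typ
    drift = 1.0 + noise.drift_sd * float(rng.standard_normal())
    raw = model * lamp * drift * gain
    sc = lamp * drift * gain * r_typ
    if noise.shot_noise:
        raw = raw + rng.standard_normal(raw.shape) * np.sqrt(np.clip(raw, 0, None))
        sc = sc + rng.standard_normal(sc.shape) * np.sqrt(np.clip(sc, 0, None))
    return {"raw": raw, "sc": sc, "model": model}


def render_phantom_spectra(
    model: PhantomOpticalModel,
    lut,
    noise_rel: float = 0.01,
    drift_sd: float = 0.009,
    seed: int = 0,
) -> dict[int, dict]:
    """Raw single-channel spectra for the 12 phantoms: model reflectance x
    lamp x drift + multiplicative noise, with matching SC spectra."""
    rng = np.random.default_rng(seed)
    grid = model.grid
    lamp = lamp_spectrum(grid)
    out = {}
    for spec in table1_phantoms():
        props = model.optical_properties(spec)
        r_true = lut(props.mu_s_prime, props.mu_a)
        drift = 1.0 + drift_sd * float(rng.standard_normal())
        raw = r_true * lamp * drift * (1.0 + noise_rel * rng.standard_normal(len(grid)))
        sc = lamp * drift * (1.0 + noise_rel / 4 * rng.standard_normal(len(grid)))
        out[spec.phantom_id] = {
            "raw": raw,
            "sc": sc,
            "true_reflectance": r_true,
            "spec": spec,
            "props": props,
        }
    return out
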