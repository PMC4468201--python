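"""Reference calibration and nonlinear least-squares spectral fitting
against the scalable-MC forward model, plus the leave-one-out phantom
accuracy harness."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .optics import DEFAULT_BAND, WavelengthGrid, band_average

#: optimizer settings (documented defaults, not fitted to any target)
FIT_FTOL = 1e-8
FIT_XTOL = 1e-8
FIT_MAX_NFEV = 500
N_MULTISTART = 3


@dataclass(frozen=True)
class CalibratedSpectrum:
    """Sample reflectance transferred onto the forward model's scale."""

    grid: WavelengthGrid
    reflectance: np.ndarray
    channel_id: str = ""
    provenance: str = ""

    def __post_init__(self):
        r = np.asarray(self.reflectance, dtype=float)
        if r.shape != (len(self.grid),):
            raise ValueError("reflectance not on the grid")
        if not np.all(np.isfinite(r)):
            raise ValueError("non-finite calibrated reflectance")
        if np.any(r < 0):
            raise ValueError("negative calibrated reflectance")
        object.__setattr__(self, "reflectance", r)


def calibrate_spectrum(
    raw_sample: np.ndarray,
    raw_reference: np.ndarray,
    model_reference: np.ndarray,
    sc_correction: tuple[np.ndarray, np.ndarray] | None = None,
    grid: WavelengthGrid | None = None,
    channel_id: str = "",
) -> CalibratedSpectrum:
    """calibrated = (raw_sample / raw_reference) * model_reference, after
    dividing sample and reference by their self-calibration spectra.

    ``sc_correction`` is (sc_sample, sc_reference); pass None when the raw
    inputs are already drift-normalized.  Global intensity drift common to
    a frame and its SC channel cancels exactly.
    """
    s = np.asarray(raw_sample, dtype=float)
    ref = np.asarray(raw_reference, dtype=float)
    model = np.asarray(model_reference, dtype=float)
    if s.shape != ref.shape or s.shape != model.shape:
        raise ValueError("spectra must share one grid")
    if sc_correction is not None:
        sc_s, sc_r = sc_correction
        sc_s = np.asarray(sc_s, dtype=float)
        sc_r = np.asarray(sc_r, dtype=float)
        if np.any(sc_s <= 0) or np.any(sc_r <= 0):
            raise ValueError("self-calibration spectra must be positive")
        s = s / sc_s
        ref = ref / sc_r
    if np.any(ref <= 0):
        raise ValueError("reference reflectance must be positive on the band")
    cal = np.clip(s / ref * model, 0.0, None)
    if grid is None:
        grid = WavelengthGrid.analysis_band()
        if len(grid) != cal.size:
            raise ValueError("pass the wavelength grid explicitly")
    return CalibratedSpectrum(grid, cal, channel_id=channel_id,
                              provenance="ratio-calibrated")


@dataclass(frozen=True)
class FitParameter:
    name: str
    init: float
    lower: float
    upper: float

    def __post_init__(self):
        if not self.lower <= self.init <= self.upper:
            raise ValueError(f"initial value of {self.name!r} outside bounds")


@dataclass(frozen=True)
class FitParameters:
    params: tuple[FitParameter, ...]

    @classmethod
    def tissue_defaults(cls):
        return cls((
            FitParameter("hb_uM", 40.0, 0.0, 300.0),
            FitParameter("bcar_uM", 10.0, 0.0, 100.0),
            FitParameter("musp_band", 9.0, 1.0, 20.0),
            FitParameter("scatter_power", 1.0, 0.0, 3.0),
        ))

    @classmethod
    def phantom_defaults(cls):
        return cls((
            FitParameter("hb_uM", 50.0, 0.0, 300.0),
            FitParameter("musp_band", 8.5, 1.0, 20.0),
        ))

    @property
    def names(self):
        return [p.name for p in self.params]

    @property
    def x0(self):
        return np.array([p.init for p in self.params])

    @property
    def bounds(self):
        return (np.array([p.lower for p in self.params]),
                np.array([p.upper for p in self.params]))


@dataclass
class FitResult:
    params: dict[str, float]
    mu_a: np.ndarray
    mu_s_prime: np.ndarray
    musp_band: float
    mua_band: float
    ratio: float  # [beta-carotene]/<mu_s'>, uM cm (NaN when not fitted)
    rss: float
    converged: bool
    n_starts: int = 1
    model: np.ndarray | None = None


def fit_spectrum(
    calibrated: CalibratedSpectrum,
    forward,
    params: FitParameters,
    n_starts: int = N_MULTISTART,
    rng: np.random.Generator | None = None,
) -> FitResult:
    """Bounded trust-region least squares of the calibrated spectrum
    against ``forward``.

    ``forward(x)`` maps a parameter vector to a model spectrum on the same
    grid and must expose ``spectra_at(x)`` returning (mu_a, mu_s_prime)
    spectra for the derived outputs.  Multi-starts jitter the initial point
    deterministically; the best residual wins, ties broken by first index.
    """
    y = calibrated.reflectance
    if np.all(y == 0):
        raise ValueError("all-zero spectrum cannot be fitted")
    rng = rng or np.random.default_rng(0)
    lo, hi = params.bounds
    x0s = [params.x0]
    for _ in range(max(0, n_starts - 1)):
        jitter = params.x0 * (1.0 + 0.2 * rng.standard_normal(len(params.params)))
        x0s.append(np.clip(jitter, lo, hi))

    scale = np.mean(y[y > 0]) if np.any(y > 0) else 1.0

    def resid(x):
        return (forward(x) - y) / scale

    best = None
    n_ok = 0
    for x0 in x0s:
        try:
            sol = least_squares(
                resid, x0, bounds=(lo, hi),
                ftol=FIT_FTOL, xtol=FIT_XTOL, max_nfev=FIT_MAX_NFEV,
            )
        except Exception:
            continue
        n_ok += 1
        if best is None or sol.cost < best.cost - 1e-15:
            best = sol
    if best is None:
        return FitResult({}, np.array([]), np.array([]), np.nan, np.nan, np.nan,
                         np.inf, False, n_starts=len(x0s))

    names = params.names
    fitted = dict(zip(names, best.x))
    mu_a, musp = forward.spectra_at(best.x)
    grid = calibrated.grid
    musp_b = band_average(musp, grid, DEFAULT_BAND)
    mua_b = band_average(mu_a, grid, DEFAULT_BAND)
    ratio = fitted.get("bcar_uM", np.nan) / musp_b if musp_b > 0 else np.nan
    return FitResult(
        params=fitted,
        mu_a=mu_a,
        mu_s_prime=musp,
        musp_band=musp_b,
        mua_band=mua_b,
        ratio=ratio,
        rss=float(2 * best.cost * scale**2),
        converged=bool(best.success) and n_ok > 0,
        n_starts=len(x0s),
        model=forward(best.x),
    )


class PhantomForward:
    """Forward model for the phantom dilution series: hemoglobin-only
    absorption and the Mie scattering shape scaled by a fitted magnitude."""

    def __init__(self, phantom_model, lut):
        self.pm = phantom_model
        self.lut = lut
        ref = self.pm._musp_ref
        self._musp_unit = ref / band_average(ref, self.pm.grid)

    def __call__(self, x):
        mu_a, musp = self.spectra_at(x)
        return self.lut(musp, mu_a)

    def spectra_at(self, x):
        hb, musp_band = x
        return self.pm.mu_a(hb), self._musp_unit * musp_band


class TissueFitForward:
    """Forward model for tissue fits: Hb + beta-carotene absorption and a
    power-law reduced-scattering spectrum through the lookup table."""

    def __init__(self, tissue_forward):
        self.tf = tissue_forward

    def __call__(self, x):
        hb, bcar, musp_band, b = x
        return self.tf.reflectance(hb, bcar, musp_band, b)[0]

    def spectra_at(self, x):
        hb, bcar, musp_band, b = x
        return (self.tf.mua_spectrum(hb, bcar)[0],
                self.tf.musp_spectrum(musp_band, b)[0])


def invert_scan(
    scan,
    tissue_forward,
    reference: dict,
    params: FitParameters | None = None,
    n_starts: int = 1,
) -> dict[tuple[int, int], dict[str, np.ndarray]]:
    """Calibrate and fit every on-tissue channel of a rendered scan.

    ``reference`` is a dict with ``raw``, ``sc`` and ``model`` spectra (a
    measurement of a medium with known properties).  Returns per-offset
    dicts of (7, 7) grids for each extracted parameter; off-tissue channels
    are NaN.
    """
    params = params or FitParameters.tissue_defaults()
    forward = TissueFitForward(tissue_forward)
    grid = tissue_forward.grid
    parity_odd = (np.indices((7, 7)).sum(axis=0) % 2 == 0).ravel()
    fields = ("hb_uM", "bcar_uM", "musp_band", "mua_band", "ratio", "rss", "converged")
    out: dict[tuple[int, int], dict[str, np.ndarray]] = {}
    for fr in scan.frames:
        grids = {f: np.full(49, np.nan) for f in fields}
        on = fr.metadata.get("on_tissue")
        on = np.ones(49, dtype=bool) if on is None else np.asarray(on).ravel()
        for ch in range(49):
            if not on[ch]:
                continue
            sc = fr.sc_odd if parity_odd[ch] else fr.sc_even
            cal = calibrate_spectrum(
                fr.spectra[ch], reference["raw"], reference["model"],
                sc_correction=(sc, reference["sc"]), grid=grid,
                channel_id=f"ch{ch + 1:02d}",
            )
            res = fit_spectrum(cal, forward, params, n_starts=n_starts)
            grids["hb_uM"][ch] = res.params.get("hb_uM", np.nan)
            grids["bcar_uM"][ch] = res.params.get("bcar_uM", np.nan)
            grids["musp_band"][ch] = res.musp_band
            grids["mua_band"][ch] = res.mua_band
            grids["ratio"][ch] = res.ratio
            grids["rss"][ch] = res.rss
            grids["converged"][ch] = float(res.converged)
        out[fr.offset_index] = {f: v.reshape(7, 7) for f, v in grids.items()}
    return out


@dataclass
class LoocvSummary:
    folds: pd.DataFrame
    mean_pct_mua: float
    sd_pct_mua: float
    mean_pct_musp: float
    sd_pct_musp: float
    zero_mua_abs_error: float  # absolute error (cm^-1) for the mu_a = 0 phantom
    n_folds: int
    n_inversions: int


def loocv_phantom_errors(
    phantom_spectra: dict[int, dict],
    phantom_model,
    lut,
    n_starts: int = N_MULTISTART,
) -> LoocvSummary:
    """12-fold leave-one-out calibration/inversion accuracy.

    Each phantom serves once as the calibration reference against the
    remaining 11 (132 inversions).  Percent error is
    100*|extracted - expected|/expected; the zero-absorption phantom is
    excluded from the mu_a percent aggregate and reported as an absolute
    error instead.
    """
    ids = sorted(phantom_spectra)
    if len(ids) < 2:
        raise ValueError("need at least 2 phantoms")
    grid = phantom_model.grid
    forward = PhantomForward(phantom_model, lut)
    fitp = FitParameters.phantom_defaults()
    rows = []
    zero_abs = []
    for ref_id in ids:
        ref = phantom_spectra[ref_id]
        model_ref = lut(ref["props"].mu_s_prime, ref["props"].mu_a)
        for tgt_id in ids:
            if tgt_id == ref_id:
                continue
            tgt = phantom_spectra[tgt_id]
            cal = calibrate_spectrum(
                tgt["raw"], ref["raw"], model_ref,
                sc_correction=(tgt["sc"], ref["sc"]), grid=grid,
                channel_id=f"phantom{tgt_id}",
            )
            res = fit_spectrum(cal, forward, fitp, n_starts=n_starts)
            spec = tgt["spec"]
            pct_musp = 100.0 * abs(res.musp_band - spec.musp_expected) / spec.musp_expected
            if spec.mua_expected > 0:
                pct_mua = 100.0 * abs(res.mua_band - spec.mua_expected) / spec.mua_expected
            else:
                pct_mua = np.nan
                zero_abs.append(abs(res.mua_band - spec.mua_expected))
            rows.append({
                "reference": ref_id, "target": tgt_id,
                "musp_extracted": res.musp_band, "musp_expected": spec.musp_expected,
                "mua_extracted": res.mua_band, "mua_expected": spec.mua_expected,
                "pct_error_musp": pct_musp, "pct_error_mua": pct_mua,
                "converged": res.converged,
            })
    df = pd.DataFrame(rows)
    mua = df["pct_error_mua"].dropna()
    return LoocvSummary(
        folds=df,
        mean_pct_mua=float(mua.mean()),
        sd_pct_mua=float(mua.std()),
        mean_pct_musp=float(df["pct_error_musp"].mean()),
        sd_pct_musp=float(df["pct_error_musp"].std()),
        zero_mua_abs_error=float(np.mean(zero_abs)) if zero_abs else np.nan,
        n_folds=len(ids),
        n_inversions=len(df),
    )
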