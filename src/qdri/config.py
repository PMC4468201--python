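"""Run configuration, validation, and the end-to-end pipeline."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import platform
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .optics import DEFAULT_BAND, G_TISSUE_DEFAULT, N_TISSUE, OpticalProperties, WavelengthGrid

log = logging.getLogger(__name__)

EXIT_OK = 0
EXIT_CONFIG = 2
EXIT_DATA = 3
EXIT_NUMERIC = 4


class ConfigError(ValueError):
    """Invalid or inconsistent run configuration."""


@dataclass
class RunConfig:
    """Single human-editable configuration for a reproducible run."""

    # spectral
    wavelength_step_nm: float = 2.0
    analysis_band: tuple[float, float] = DEFAULT_BAND
    # probe
    pitch_mm: float = 6.0
    sds_um: float = 700.0
    fiber_diameter_um: float = 200.0
    numerical_aperture: float = 0.22
    # monte carlo
    mc_photons: int = 400_000
    mc_seed: int = 7
    baseline_musp: float = 10.0
    anisotropy: float = G_TISSUE_DEFAULT
    n_tissue: float = N_TISSUE
    # fitting
    fit_multistarts: int = 1
    # scan / synthesis
    upsample_factor: int = 4
    stratum: str = "LBD"
    margin_seed: int = 3
    render_seed: int = 5
    drift_sd: float = 0.009
    # output
    out_dir: str = "qdri_run"

    def validate(self) -> "RunConfig":
        if self.wavelength_step_nm <= 0:
            raise ConfigError("wavelength_step_nm must be positive")
        lo, hi = self.analysis_band
        if not (420 <= lo < hi <= 700):
            raise ConfigError("analysis_band must lie within 420-700 nm")
        if self.mc_photons < 1:
            raise ConfigError("mc_photons must be >= 1")
        if self.upsample_factor < 1 or int(self.upsample_factor) != self.upsample_factor:
            raise ConfigError("upsample_factor must be a positive integer")
        if self.stratum not in ("LBD", "HBD"):
            raise ConfigError("stratum must be LBD or HBD")
        if not (-1 < self.anisotropy < 1):
            raise ConfigError("anisotropy must lie in (-1, 1)")
        if not (0 <= self.drift_sd <= 0.02):
            raise ConfigError("drift_sd must lie in [0, 0.02]")
        return self

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "analysis_band" in d:
            d = dict(d)
            d["analysis_band"] = tuple(d["analysis_band"])
        return cls(**d).validate()

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(path)
        data = yaml.safe_load(path.read_text()) or {}
        if not isinstance(data, dict):
            raise ConfigError("config file must hold a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["analysis_band"] = list(d["analysis_band"])
        return d

    def grid(self) -> WavelengthGrid:
        return WavelengthGrid.default(
            self.analysis_band[0], self.analysis_band[1], self.wavelength_step_nm
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Synthetic margin -> rendered scan -> inversion -> stitched maps ->
    landscape report; deterministic for fixed config seeds.

    Returns the manifest (also written to ``manifest.json``).
    """
    from .inversion import invert_scan
    from .io import write_map, write_scan_dir
    from .landscape import ecdf, ratio_map
    from .mc import ChannelGeometry, LayeredMedium, ReflectanceLUT, run_mc
    from .scan import ParameterMap, RasterPlan, segment_margin, stitch
    from .synthetic import (
        NoiseModel,
        TissueForward,
        generate_margin,
        render_frames,
        render_reference,
    )

    config.validate()
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    grid = config.grid()
    geometry = ChannelGeometry(
        sds_um=config.sds_um,
        fiber_diameter_um=config.fiber_diameter_um,
        numerical_aperture=config.numerical_aperture,
        pitch_mm=config.pitch_mm,
    )
    base_props = OpticalProperties(
        [0.0], [config.baseline_musp], [config.anisotropy], config.n_tissue
    )
    log.info("baseline MC: %d photons, seed %d", config.mc_photons, config.mc_seed)
    baseline = run_mc(
        LayeredMedium.semi_infinite(base_props), config.mc_photons, config.mc_seed
    )
    lut = ReflectanceLUT(baseline, geometry)
    forward = TissueForward(lut, grid)

    margin = generate_margin(config.stratum, seed=config.margin_seed)
    plan = RasterPlan(int(config.upsample_factor), config.pitch_mm)
    noise = NoiseModel(drift_sd=config.drift_sd)
    scan = render_frames(margin, plan, forward, noise=noise, seed=config.render_seed)
    write_scan_dir(scan, out / "scan")

    reference = render_reference(forward, noise=noise, seed=config.render_seed + 1)
    tables = invert_scan(scan, forward, reference, n_starts=config.fit_multistarts)

    maps = {}
    for param in ("bcar_uM", "musp_band", "hb_uM"):
        pmap = stitch({k: v[param] for k, v in tables.items()}, plan, label=param)
        maps[param] = pmap
        write_map(pmap, out / f"map_{param}")
    rmap = ratio_map(maps["bcar_uM"], maps["musp_band"])
    write_map(rmap, out / "map_ratio")

    mask = segment_margin(
        ParameterMap(np.nan_to_num(rmap.values), rmap.pitch_mm, "ratio")
    )
    vals = rmap.values[mask & np.isfinite(rmap.values)]
    report = {}
    if vals.size:
        dist = ecdf(vals, provenance=f"margin:{config.stratum}")
        dist.table().to_csv(out / "ecdf_ratio.csv", index=False)
        report = {
            "n_pixels": int(dist.n),
            "median_ratio": float(np.median(dist.values)),
            "iqr": [float(np.quantile(dist.values, q)) for q in (0.25, 0.75)],
        }

    manifest = {
        "qdri_version": __version__,
        "python": platform.python_version(),
        "config": config.to_dict(),
        "seeds": {
            "mc": config.mc_seed,
            "margin": config.margin_seed,
            "render": config.render_seed,
        },
        "landscape": report,
        "checksums": {
            p.name: _sha256(p) for p in sorted(out.glob("*.csv"))
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
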