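"""Forward photon transport driver and its domain types."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..optics import OpticalProperties
from . import _kernel

#: roulette settings (documented defaults)
ROULETTE_THRESHOLD = 1e-4
ROULETTE_SURVIVAL = 0.1
#: effective semi-infinite cutoffs: photons crossing these leave the ledger
#: as transmitted/leaked; negligible for collection within 2 cm of the source
MAX_DEPTH_CM = 1.2
MAX_RADIUS_CM = 3.0
MAX_STEPS = 10_000_000

N_AMBIENT = 1.0  # NA acceptance is evaluated in air above the surface


@dataclass(frozen=True)
class ChannelGeometry:
    """One probe channel: 8 illumination fibers on a ring around a single
    detection fiber."""

    sds_um: float = 700.0
    fiber_diameter_um: float = 200.0
    numerical_aperture: float = 0.22
    n_illumination_fibers: int = 8
    pitch_mm: float = 6.0

    def __post_init__(self):
        if self.sds_um <= self.fiber_diameter_um / 2:
            raise ValueError("source-detector separation must exceed fiber radius")
        if self.pitch_mm <= 0:
            raise ValueError("channel pitch must be positive")

    @property
    def sds_cm(self) -> float:
        return self.sds_um * 1e-4

    @property
    def fiber_radius_cm(self) -> float:
        return self.fiber_diameter_um * 1e-4 / 2.0


@dataclass(frozen=True)
class LayeredMedium:
    """Ordered stack of homogeneous layers; the last layer is semi-infinite.

    ``layers`` is a list of (OpticalProperties, thickness_cm); the thickness
    of the last layer is ignored (may be None / inf).
    """

    layers: tuple
    n_ambient: float = N_AMBIENT

    def __post_init__(self):
        if len(self.layers) < 1:
            raise ValueError("at least one layer required")
        for props, thick in self.layers[:-1]:
            if thick is None or thick <= 0:
                raise ValueError("finite layers need positive thickness")
        object.__setattr__(self, "layers", tuple(self.layers))

    @classmethod
    def semi_infinite(cls, props: OpticalProperties, n_ambient: float = N_AMBIENT):
        return cls(((props, None),), n_ambient=n_ambient)


@dataclass(frozen=True)
class PhotonExitRecord:
    """A single photon leaving through the top surface."""

    exit_radius_cm: float
    exit_cosine: float
    weight: float
    path_length_per_layer_cm: np.ndarray

    def __post_init__(self):
        if not (0 < self.weight <= 1.0 + 1e-12):
            raise ValueError("weight must lie in (0, 1]")
        if self.exit_radius_cm < 0:
            raise ValueError("exit radius must be non-negative")
        if np.any(np.asarray(self.path_length_per_layer_cm) < 0):
            raise ValueError("path lengths must be non-negative")


@dataclass
class BaselineSimulation:
    """Exit-record cache from one forward run (the scalable-MC substrate)."""

    exit_radius: np.ndarray
    exit_cosine: np.ndarray
    weight: np.ndarray
    path_lengths: np.ndarray  # (n_exit, n_layers)
    mu_a: np.ndarray
    mu_s: np.ndarray
    g: np.ndarray
    n_layers_index: np.ndarray
    n_ambient: float
    photon_count: int
    seed: int
    ledger: dict = field(default_factory=dict)
    schema_version: str = "baseline-cache-1"

    @property
    def n_records(self) -> int:
        return self.exit_radius.size

    @property
    def total_path(self) -> np.ndarray:
        return self.path_lengths.sum(axis=1)

    def record(self, i: int) -> PhotonExitRecord:
        return PhotonExitRecord(
            float(self.exit_radius[i]),
            float(self.exit_cosine[i]),
            float(self.weight[i]),
            self.path_lengths[i],
        )

    def diffuse_reflectance(self) -> float:
        """Total exiting weight per launched photon."""
        return float(self.weight.sum() / self.photon_count)

    def save(self, path):
        import h5py

        with h5py.File(path, "w") as f:
            f.attrs["schema_version"] = self.schema_version
            f.attrs["photon_count"] = self.photon_count
            f.attrs["seed"] = self.seed
            f.attrs["n_ambient"] = self.n_ambient
            for k, v in self.ledger.items():
                f.attrs[f"ledger_{k}"] = v
            for name in ("exit_radius", "exit_cosine", "weight", "path_lengths",
                         "mu_a", "mu_s", "g", "n_layers_index"):
                f.create_dataset(name, data=getattr(self, name))

    @classmethod
    def load(cls, path):
        import h5py

        with h5py.File(path, "r") as f:
            ledger = {
                k[len("ledger_"):]: float(v)
                for k, v in f.attrs.items()
                if k.startswith("ledger_")
            }
            return cls(
                exit_radius=f["exit_radius"][:],
                exit_cosine=f["exit_cosine"][:],
                weight=f["weight"][:],
                path_lengths=f["path_lengths"][:],
                mu_a=f["mu_a"][:],
                mu_s=f["mu_s"][:],
                g=f["g"][:],
                n_layers_index=f["n_layers_index"][:],
                n_ambient=float(f.attrs["n_ambient"]),
                photon_count=int(f.attrs["photon_count"]),
                seed=int(f.attrs["seed"]),
                ledger=ledger,
                schema_version=str(f.attrs["schema_version"]),
            )


def _medium_arrays(medium: LayeredMedium, wavelength_index: int):
    """Flatten a LayeredMedium into per-layer scalar arrays at one
    wavelength index of each layer's property spectra."""
    L = len(medium.layers)
    mua = np.empty(L)
    mus = np.empty(L)
    g = np.empty(L)
    n = np.empty(L)
    z_bounds = np.empty(L)
    z = 0.0
    for i, (props, thick) in enumerate(medium.layers):
        j = min(wavelength_index, props.mu_a.size - 1)
        mua[i] = props.mu_a[j]
        mus[i] = props.mu_s[j]
        g[i] = props.g[j]
        n[i] = props.n_medium
        if i < L - 1:
            z += thick
            z_bounds[i] = z
        else:
            z_bounds[i] = max(MAX_DEPTH_CM, z + 1e-6)
    if np.any(mus <= 0):
        raise ValueError("each layer needs mu_s > 0")
    if np.any(mua < 0):
        raise ValueError("mu_a must be non-negative")
    return mua, mus, g, n, z_bounds


def run_mc(
    medium: LayeredMedium,
    n_photons: int,
    seed: int,
    wavelength_index: int = 0,
    max_depth_cm: float | None = None,
    max_radius_cm: float = MAX_RADIUS_CM,
) -> BaselineSimulation:
    """Trace ``n_photons`` pencil-beam photons and collect top-surface exit
    records.  Reproducible for a fixed seed."""
    if n_photons < 1:
        raise ValueError("n_photons must be >= 1")
    mua, mus, g, n, z_bounds = _medium_arrays(medium, wavelength_index)
    if max_depth_cm is not None:
        z_bounds[-1] = max_depth_cm
    n_exit, r, uz, w, paths, ledger = _kernel.transport(
        int(n_photons),
        mua,
        mus,
        g,
        n,
        z_bounds,
        medium.n_ambient,
        int(seed),
        ROULETTE_THRESHOLD,
        ROULETTE_SURVIVAL,
        MAX_STEPS,
        max_radius_cm,
    )
    led = dict(zip(_kernel.LEDGER_FIELDS, ledger))
    led["launched"] = float(n_photons)
    return BaselineSimulation(
        exit_radius=r[:n_exit].copy(),
        exit_cosine=uz[:n_exit].copy(),
        weight=w[:n_exit].copy(),
        path_lengths=paths[:n_exit].copy(),
        mu_a=mua,
        mu_s=mus,
        g=g,
        n_layers_index=n,
        n_ambient=medium.n_ambient,
        photon_count=int(n_photons),
        seed=int(seed),
        ledger=led,
    )


def energy_balance(sim: BaselineSimulation) -> float:
    """launched - (specular + reflected + transmitted + absorbed +
    roulette_killed - roulette_gain + leaked); ~0 up to float rounding."""
    led = sim.ledger
    out = (
        led["specular"]
        + led["reflected"]
        + led["transmitted"]
        + led["absorbed"]
        + led["roulette_killed"]
        - led["roulette_gain"]
        + led["leaked"]
    )
    return led["launched"] - out
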