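"""Independent oracles, deliberately implemented by different routes than
the package code they check."""

import numpy as np
from scipy.special import spherical_jn, spherical_yn


def mie_q_sca_g_bessel(m: complex, x: float) -> tuple[float, float]:
    """Brute-force Mie partial-wave sum with the coefficients a_n, b_n built
    directly from scipy spherical Bessel functions (no logarithmic
    derivative recurrence)."""
    nmax = int(np.ceil(x + 4.05 * x ** (1 / 3) + 2)) + 1
    n = np.arange(1, nmax + 1)

    def psi(order, z):
        return z * spherical_jn(order, z)

    def psi_d(order, z):
        return spherical_jn(order, z) + z * spherical_jn(order, z, derivative=True)

    def xi(order, z):
        return z * (spherical_jn(order, z) + 1j * spherical_yn(order, z))

    def xi_d(order, z):
        return (
            spherical_jn(order, z)
            + 1j * spherical_yn(order, z)
            + z * (spherical_jn(order, z, derivative=True)
                   + 1j * spherical_yn(order, z, derivative=True))
        )

    mx = m * x
    if np.iscomplexobj(np.asarray(m)) and np.imag(m) != 0:
        raise NotImplementedError("oracle covers real indices only")
    mx = float(np.real(mx))
    a = np.empty(nmax, dtype=complex)
    b = np.empty(nmax, dtype=complex)
    for k, order in enumerate(n):
        pmx, pdmx = psi(order, mx), psi_d(order, mx)
        px, pdx = psi(order, x), psi_d(order, x)
        xx, xdx = xi(order, x), xi_d(order, x)
        a[k] = (m * pmx * pdx - px * pdmx) / (m * pmx * xdx - xx * pdmx)
        b[k] = (pmx * pdx - m * px * pdmx) / (pmx * xdx - m * xx * pdmx)

    q_sca = (2.0 / x**2) * np.sum((2 * n + 1) * (np.abs(a) ** 2 + np.abs(b) ** 2))
    nn = n[:-1].astype(float)
    t1 = nn * (nn + 2) / (nn + 1) * np.real(a[:-1] * np.conj(a[1:]) + b[:-1] * np.conj(b[1:]))
    t2 = (2 * n + 1) / (n * (n + 1)) * np.real(a * np.conj(b))
    g = 4.0 / (x**2 * q_sca) * (t1.sum() + t2.sum())
    return float(q_sca), float(g)


def ecdf_counting(values: np.ndarray, probes: np.ndarray) -> np.ndarray:
    """F(x) by explicit counting."""
    values = np.asarray(values, dtype=float)
    return np.array([(values <= x).sum() / values.size for x in probes])


def ks_d_exhaustive(a: np.ndarray, b: np.ndarray) -> float:
    """sup |F_a - F_b| by evaluating both counting eCDFs at every pooled
    sample point."""
    a = np.sort(np.asarray(a, dtype=float))
    b = np.sort(np.asarray(b, dtype=float))
    best = 0.0
    for x in np.concatenate([a, b]):
        fa = (a <= x).sum() / a.size
        fb = (b <= x).sum() / b.size
        best = max(best, abs(fa - fb))
    return best


def channel_reflectance_se(records, geometry, n_batches=20):
    """Batch-means Monte Carlo standard error of the kernel-collected
    channel reflectance."""
    from qdri.mc.forward import KERNEL_R_MAX_CM, KERNEL_R_STEP_CM, _na_accept, collection_kernel

    keep = _na_accept(records.exit_cosine, geometry)
    r = records.exit_radius[keep]
    w = records.weight[keep]
    r_grid = np.arange(0.0, KERNEL_R_MAX_CM + KERNEL_R_STEP_CM, KERNEL_R_STEP_CM)
    kern = collection_kernel(
        r_grid, geometry.sds_cm, geometry.fiber_radius_cm, geometry.fiber_radius_cm
    )
    contrib = w * np.interp(r, r_grid, kern, right=0.0)
    edges = np.linspace(0, contrib.size, n_batches + 1, dtype=int)
    per_photon = records.photon_count / n_batches
    vals = np.array(
        [contrib[edges[i]:edges[i + 1]].sum() / per_photon for i in range(n_batches)]
    )
    return float(vals.std(ddof=1) / np.sqrt(n_batches))
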