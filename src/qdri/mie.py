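"""Mie scattering for homogeneous spheres.

Classic Lorenz-Mie partial-wave solution using the logarithmic-derivative
downward recurrence for the internal field and upward recurrence for the
Riccati-Bessel functions (Bohren & Huffman style).  Only the quantities
needed for transport modelling are exposed: the scattering efficiency
``Q_sca`` and the asymmetry parameter ``g``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["mie_q_sca_g"]


def _n_terms(x: float) -> int:
    # Wiscombe series-truncation criterion
    return int(np.ceil(x + 4.05 * x ** (1.0 / 3.0) + 2.0)) + 1


def mie_q_sca_g(m: complex, x: float) -> tuple[float, float]:
    """Scattering efficiency and asymmetry parameter for size parameter ``x``
    and relative refractive index ``m`` (sphere index / medium index).

    Parameters
    ----------
    m : complex
        Relative refractive index; imaginary part ≥ 0 for absorbing spheres.
    x : float
        Size parameter ``pi * diameter * n_medium / wavelength``.

    Returns
    -------
    (q_sca, g)
    """
    if x <= 0:
        raise ValueError("size parameter must be positive")
    if np.real(m) < 1.0 and np.imag(m) == 0 and abs(m) < 1.0:
        # relative index below 1 is physical (bubbles) but outside the
        # validated use of this routine
        raise ValueError("relative refractive index < 1 is not supported")
    nmax = _n_terms(x)
    mx = m * x

    # downward recurrence for the logarithmic derivative D_n(mx)
    nstart = nmax + int(np.ceil(np.abs(mx))) + 16
    d = np.zeros(nstart + 1, dtype=complex)
    for n in range(nstart, 0, -1):
        d[n - 1] = n / mx - 1.0 / (d[n] + n / mx)

    a = np.zeros(nmax, dtype=complex)
    b = np.zeros(nmax, dtype=complex)
    # Riccati-Bessel psi, chi by upward recurrence
    psi_nm1 = np.sin(x)          # psi_0
    psi_nm2 = np.cos(x)          # psi_{-1}
    chi_nm1 = np.cos(x)          # chi_0
    chi_nm2 = -np.sin(x)         # chi_{-1}
    for n in range(1, nmax + 1):
        psi = (2 * n - 1) / x * psi_nm1 - psi_nm2
        chi = (2 * n - 1) / x * chi_nm1 - chi_nm2
        xi = psi - 1j * chi
        xi_nm1 = psi_nm1 - 1j * chi_nm1
        dn = d[n]
        da = dn / m + n / x
        db = dn * m + n / x
        a[n - 1] = (da * psi - psi_nm1) / (da * xi - xi_nm1)
        b[n - 1] = (db * psi - psi_nm1) / (db * xi - xi_nm1)
        psi_nm2, psi_nm1 = psi_nm1, psi
        chi_nm2, chi_nm1 = chi_nm1, chi

    n = np.arange(1, nmax + 1, dtype=float)
    q_sca = (2.0 / x**2) * np.sum((2 * n + 1) * (np.abs(a) ** 2 + np.abs(b) ** 2))

    # asymmetry parameter (Bohren & Huffman eq. 4.62)
    an, bn = a[:-1], b[:-1]
    an1, bn1 = a[1:], b[1:]
    nn = n[:-1]
    t1 = nn * (nn + 2.0) / (nn + 1.0) * np.real(an * np.conj(an1) + bn * np.conj(bn1))
    t2 = (2 * n + 1) / (n * (n + 1)) * np.real(a * np.conj(b))
    g = (4.0 / (x**2 * q_sca)) * (np.sum(t1) + np.sum(t2))
    return float(q_sca), float(g)
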