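"""Numba transport kernel: hop-drop-spin with Henyey-Greenstein phase
function, Fresnel boundaries and Russian-roulette termination.

Layout conventions
------------------
The medium occupies z > 0; photons are launched at the origin pointing +z
(pencil beam).  Layers are indexed top to bottom; ``z_bounds[i]`` is the
depth of the *lower* boundary of layer ``i``.  The last entry acts as a
hard transmission cutoff standing in for a semi-infinite bottom layer.

Ledger indices (see :data:`LEDGER_FIELDS`): launched weight splits exactly
into specular + diffuse-reflected + transmitted + absorbed + roulette_killed
- roulette_gain + leaked.
"""

import math

import numpy as np
from numba import njit

LEDGER_FIELDS = (
    "specular",
    "reflected",
    "transmitted",
    "absorbed",
    "roulette_killed",
    "roulette_gain",
    "leaked",
)

_I_SPEC, _I_REFL, _I_TRAN, _I_ABS, _I_RKILL, _I_RGAIN, _I_LEAK = range(7)


@njit(cache=True, fastmath=True)
def _fresnel(n_i, n_t, ci):
    """Unpolarized Fresnel reflectance for incidence cosine ``ci`` (>0).

    Returns (R, ct) where ct is the transmitted cosine (0 if TIR).
    """
    if n_i == n_t:
        return 0.0, ci
    si = math.sqrt(max(0.0, 1.0 - ci * ci))
    st = n_i / n_t * si
    if st >= 1.0:
        return 1.0, 0.0
    ct = math.sqrt(1.0 - st * st)
    rs = (n_i * ci - n_t * ct) / (n_i * ci + n_t * ct)
    rp = (n_i * ct - n_t * ci) / (n_i * ct + n_t * ci)
    return 0.5 * (rs * rs + rp * rp), ct


@njit(cache=True, fastmath=True)
def _spin(ux, uy, uz, g):
    """Sample a Henyey-Greenstein deflection and rotate the direction."""
    if g == 0.0:
        cos_t = 2.0 * np.random.random() - 1.0
    else:
        tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * np.random.random())
        cos_t = (1.0 + g * g - tmp * tmp) / (2.0 * g)
        if cos_t > 1.0:
            cos_t = 1.0
        elif cos_t < -1.0:
            cos_t = -1.0
    sin_t = math.sqrt(max(0.0, 1.0 - cos_t * cos_t))
    phi = 2.0 * math.pi * np.random.random()
    cos_p = math.cos(phi)
    sin_p = math.sin(phi)
    if abs(uz) > 0.99999:
        nux = sin_t * cos_p
        nuy = sin_t * sin_p
        nuz = cos_t * (1.0 if uz >= 0.0 else -1.0)
    else:
        den = math.sqrt(1.0 - uz * uz)
        nux = sin_t * (ux * uz * cos_p - uy * sin_p) / den + ux * cos_t
        nuy = sin_t * (uy * uz * cos_p + ux * sin_p) / den + uy * cos_t
        nuz = -sin_t * cos_p * den + uz * cos_t
    norm = math.sqrt(nux * nux + nuy * nuy + nuz * nuz)
    return nux / norm, nuy / norm, nuz / norm


@njit(cache=True, fastmath=True)
def transport(
    n_photons,
    mua,
    mus,
    g,
    n_layer,
    z_bounds,
    n_ambient,
    seed,
    roulette_threshold,
    roulette_survival,
    max_steps,
    r_escape,
):
    """Trace ``n_photons`` through the layer stack.

    Returns
    -------
    (n_exit, exit_r, exit_uz, exit_w, exit_path, ledger)
        Arrays are over-allocated to ``n_photons``; only the first
        ``n_exit`` rows are valid.  ``exit_uz`` is the direction cosine
        w.r.t. the surface normal *after refraction into the ambient*.
        ``exit_path`` holds the geometric path length spent in each layer.
    """
    np.random.seed(seed)
    n_lay = mua.shape[0]
    exit_r = np.empty(n_photons, dtype=np.float64)
    exit_uz = np.empty(n_photons, dtype=np.float64)
    exit_w = np.empty(n_photons, dtype=np.float64)
    exit_path = np.empty((n_photons, n_lay), dtype=np.float64)
    ledger = np.zeros(7, dtype=np.float64)
    n_exit = 0

    # specular reflection at normal incidence on entry
    r0 = (n_ambient - n_layer[0]) / (n_ambient + n_layer[0])
    rsp = r0 * r0
    w_launch = 1.0 - rsp

    path = np.zeros(n_lay, dtype=np.float64)

    for _ in range(n_photons):
        ledger[_I_SPEC] += rsp
        x = 0.0
        y = 0.0
        z = 0.0
        ux = 0.0
        uy = 0.0
        uz = 1.0
        w = w_launch
        lay = 0
        for k in range(n_lay):
            path[k] = 0.0
        s_left = -math.log(np.random.random())
        alive = True
        steps = 0
        while alive:
            steps += 1
            if steps > max_steps:
                ledger[_I_LEAK] += w
                alive = False
                break
            mt = mua[lay] + mus[lay]
            s = s_left / mt
            # distance to the boundary along the current direction
            if uz > 0.0:
                db = (z_bounds[lay] - z) / uz
            elif uz < 0.0:
                zt = 0.0 if lay == 0 else z_bounds[lay - 1]
                db = (zt - z) / uz
            else:
                db = 1.0e30
            if s < db:
                x += ux * s
                y += uy * s
                z += uz * s
                path[lay] += s
                if x * x + y * y > r_escape * r_escape:
                    # wandered far outside the collection footprint
                    ledger[_I_LEAK] += w
                    alive = False
                    continue
                dw = w * mua[lay] / mt
                w -= dw
                ledger[_I_ABS] += dw
                ux, uy, uz = _spin(ux, uy, uz, g[lay])
                s_left = -math.log(np.random.random())
                if w < roulette_threshold:
                    if np.random.random() < roulette_survival:
                        gain = w * (1.0 / roulette_survival - 1.0)
                        ledger[_I_RGAIN] += gain
                        w += gain
                    else:
                        ledger[_I_RKILL] += w
                        alive = False
            else:
                x += ux * db
                y += uy * db
                path[lay] += db
                s_left -= db * mt
                going_down = uz > 0.0
                if going_down:
                    z = z_bounds[lay]
                    if lay == n_lay - 1:
                        # bottom cutoff of the (semi-infinite) last layer
                        ledger[_I_TRAN] += w
                        alive = False
                    else:
                        n_i = n_layer[lay]
                        n_t = n_layer[lay + 1]
                        refl, ct = _fresnel(n_i, n_t, abs(uz))
                        if np.random.random() < refl:
                            uz = -uz
                        else:
                            if n_i != n_t:
                                scale = n_i / n_t
                                ux *= scale
                                uy *= scale
                                uz = ct
                            lay += 1
                else:
                    z = 0.0 if lay == 0 else z_bounds[lay - 1]
                    if lay == 0:
                        n_i = n_layer[0]
                        refl, ct = _fresnel(n_i, n_ambient, abs(uz))
                        if np.random.random() < refl:
                            uz = -uz
                        else:
                            ledger[_I_REFL] += w
                            exit_r[n_exit] = math.sqrt(x * x + y * y)
                            exit_uz[n_exit] = ct
                            exit_w[n_exit] = w
                            for k in range(n_lay):
                                exit_path[n_exit, k] = path[k]
                            n_exit += 1
                            alive = False
                    else:
                        n_i = n_layer[lay]
                        n_t = n_layer[lay - 1]
                        refl, ct = _fresnel(n_i, n_t, abs(uz))
                        if np.random.random() < refl:
                            uz = -uz
                        else:
                            if n_i != n_t:
                                scale = n_i / n_t
                                ux *= scale
                                uy *= scale
                                uz = -ct
                            lay -= 1
    return n_exit, exit_r, exit_uz, exit_w, exit_path, ledger
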