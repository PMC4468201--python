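"""Landscape analysis: ratio maps, empirical CDFs, two-sample KS
comparisons, and breast-density stratification."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .scan import ParameterMap

log = logging.getLogger(__name__)

#: reduced-scattering floor below which the ratio is masked, cm^-1
RATIO_EPS = 0.01

VALID_SITE_LABELS = (
    "adipose",
    "fibroadipose",
    "fibroglandular",
    "fat_fibroglandular",
    "dcis",
)


@dataclass(frozen=True)
class DensityStratum:
    """Mammographic-density stratum: scores 1-2 bin to LBD, 3-4 to HBD."""

    mbd_score: int

    def __post_init__(self):
        if self.mbd_score not in (1, 2, 3, 4):
            raise ValueError("MBD score must be 1, 2, 3 or 4")

    @property
    def label(self) -> str:
        return "LBD" if self.mbd_score <= 2 else "HBD"


@dataclass(frozen=True)
class SiteRegion:
    """One native-channel footprint on a stitched map."""

    center_row: int
    center_col: int
    label: str
    site_id: str = ""

    def __post_init__(self):
        if self.label not in VALID_SITE_LABELS:
            raise ValueError(f"unknown site label {self.label!r}")

    def window(self, pmap: ParameterMap, upsample_factor: int) -> np.ndarray:
        """The n x n pixel block centred on the site's native channel."""
        n = upsample_factor
        r0 = self.center_row - n // 2
        c0 = self.center_col - n // 2
        if r0 < 0 or c0 < 0 or r0 + n > pmap.shape[0] or c0 + n > pmap.shape[1]:
            raise ValueError("site window outside map bounds")
        return pmap.values[r0 : r0 + n, c0 : c0 + n]


@dataclass
class LandscapeDistribution:
    """Sorted sample values with their right-continuous empirical CDF."""

    values: np.ndarray
    provenance: str = ""

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        v = v[np.isfinite(v)]
        if v.size < 1:
            raise ValueError("empty landscape distribution")
        object.__setattr__(self, "values", np.sort(v))

    @property
    def n(self) -> int:
        return self.values.size

    def cdf(self, x) -> np.ndarray:
        """F(x) = (# values <= x) / N, right-continuous with jumps 1/N."""
        x = np.asarray(x, dtype=float)
        return np.searchsorted(self.values, x, side="right") / self.n

    def table(self) -> pd.DataFrame:
        return pd.DataFrame({"x": self.values, "F": self.cdf(self.values)})


def ratio_map(bcar_map: ParameterMap, musp_map: ParameterMap, eps: float = RATIO_EPS) -> ParameterMap:
    """Elementwise [beta-carotene]/<mu_s'> map; low-scattering pixels are
    masked rather than divided."""
    if bcar_map.shape != musp_map.shape:
        raise ValueError("maps must be co-registered (same shape)")
    b = bcar_map.values
    s = musp_map.values
    good = np.isfinite(b) & np.isfinite(s) & (s > eps)
    out = np.full(b.shape, np.nan)
    out[good] = b[good] / s[good]
    mask = good.copy()
    for m in (bcar_map.mask, musp_map.mask):
        if m is not None:
            mask &= m
            out[~m] = np.nan
    return ParameterMap(out, pitch_mm=bcar_map.pitch_mm, label="bcar_over_musp",
                        units="uM cm", mask=mask)


def ecdf(values, provenance: str = "") -> LandscapeDistribution:
    return LandscapeDistribution(np.asarray(values, dtype=float), provenance)


def ks_two_sample(
    a: LandscapeDistribution | np.ndarray,
    b: LandscapeDistribution | np.ndarray,
    mode: str = "asymptotic",
) -> tuple[float, float]:
    """Two-sided two-sample Kolmogorov-Smirnov test.

    D is the exact supremum of |F_a - F_b| over the pooled sample points;
    the p-value comes from the asymptotic Kolmogorov distribution with
    effective size ``n_a n_b / (n_a + n_b)`` (``mode='exact'`` delegates to
    an exact small-sample computation instead).
    """
    if not isinstance(a, LandscapeDistribution):
        a = LandscapeDistribution(np.asarray(a, dtype=float))
    if not isinstance(b, LandscapeDistribution):
        b = LandscapeDistribution(np.asarray(b, dtype=float))
    pooled = np.concatenate([a.values, b.values])
    d = float(np.max(np.abs(a.cdf(pooled) - b.cdf(pooled))))
    ne = a.n * b.n / (a.n + b.n)
    if mode == "exact":
        res = stats.ks_2samp(a.values, b.values, method="exact")
        return d, float(res.pvalue)
    if mode != "asymptotic":
        raise ValueError("mode must be 'asymptotic' or 'exact'")
    # small-sample-corrected asymptotic argument (standard practice)
    lam = (np.sqrt(ne) + 0.12 + 0.11 / np.sqrt(ne)) * d
    p = float(special.kolmogorov(lam))
    return d, min(max(p, 0.0), 1.0)


def compare_strata(
    groups: Mapping[str, Sequence[np.ndarray]],
    min_n: int = 5,
    mode: str = "asymptotic",
) -> pd.DataFrame:
    """All pairwise KS tests between groups of pooled pixel vectors.

    Each group's member arrays are pooled into one distribution.  Groups
    whose pooled count falls below ``min_n`` are excluded with a logged
    reason.
    """
    pooled: dict[str, LandscapeDistribution] = {}
    for name, arrays in groups.items():
        vals = np.concatenate([np.ravel(np.asarray(x, dtype=float)) for x in arrays]) \
            if len(arrays) else np.array([])
        vals = vals[np.isfinite(vals)]
        if vals.size < min_n:
            log.warning("group %r excluded: pooled n=%d < %d", name, vals.size, min_n)
            continue
        pooled[name] = LandscapeDistribution(vals, provenance=name)
    if len(pooled) < 2:
        raise ValueError("fewer than 2 eligible groups")
    rows = []
    names = list(pooled)
    for i, ga in enumerate(names):
        for gb in names[i + 1 :]:
            d, p = ks_two_sample(pooled[ga], pooled[gb], mode=mode)
            rows.append({
                "group_a": ga, "group_b": gb, "D": d, "p": p,
                "n_a": pooled[ga].n, "n_b": pooled[gb].n,
            })
    return pd.DataFrame(rows)
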