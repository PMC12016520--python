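"""δ/α/ε algebra, weighted means, ring indices, and ring differences.

This module holds the arithmetic at the heart of compound-specific
hydrogen-isotope work on GDGT-derived biphytanes:

* delta notation, δ²H = (R_sample/R_standard − 1)·1000, and its inverse;
* the lipid/water fractionation ²ε_L/W = (²α_L/W − 1)·1000 with
  ²α_L/W = (1000 + δ²H_BP)/(1000 + δ²H_W);
* inverse-variance (1/σ²) weighted means with the conservative error rule
  (report the larger of the replicate scatter and the propagated σ);
* abundance-weighted means over biphytane moieties with the >5 % relative
  abundance inclusion rule;
* ring indices for biphytane (BP-0..BP-3) and iGDGT (0..8) distributions;
* the ring difference Δε/ring, the change in ²ε_L/W per additional
  cyclopentane ring, as the mean over all pairwise moiety combinations,
  and the companion regression slope of ε on ring number used for
  treatment-level summaries.

All σ propagation is first order with inputs assumed uncorrelated.
"""

from __future__ import annotations

import math
import warnings
from typing import Mapping, Sequence

import numpy as np

from .datatypes import BiphytaneProfile, IsotopeValue
from .exceptions import BpisoError

__all__ = [
    "delta_from_ratio",
    "ratio_from_delta",
    "epsilon_lw",
    "delta_bp_from_epsilon",
    "weighted_mean",
    "abundance_weighted_mean",
    "ring_index_bp",
    "ring_index_gdgt",
    "ring_difference",
    "ring_epsilon_slope",
    "ABUNDANCE_THRESHOLD",
]

#: moieties at or below this relative abundance are excluded from
#: abundance-weighted means (the ">5%" inclusion rule)
ABUNDANCE_THRESHOLD = 0.05


def delta_from_ratio(ratio_sample: float, ratio_standard: float) -> float:
    """δ (‰) from an isotope ratio and the standard's ratio."""
    if ratio_sample <= 0 or ratio_standard <= 0:
        raise ValueError("isotope ratios must be positive")
    return (ratio_sample / ratio_standard - 1.0) * 1000.0


def ratio_from_delta(delta: float, ratio_standard: float = 1.0) -> float:
    """Isotope ratio from δ (‰); inverse of :func:`delta_from_ratio`."""
    ratio = (1.0 + delta / 1000.0) * ratio_standard
    if ratio <= 0:
        raise ValueError(f"δ = {delta}‰ implies a non-positive ratio")
    return ratio


def epsilon_lw(delta_bp: IsotopeValue, delta_water: IsotopeValue) -> IsotopeValue:
    """Lipid/water fractionation ²ε_L/W (‰) from lipid and water δ²H.

    ε = ((1000 + δ_BP)/(1000 + δ_W) − 1)·1000, with σ propagated to first
    order in both inputs (treated as uncorrelated).
    """
    db, dw = delta_bp.value, delta_water.value
    if db <= -1000.0 or dw <= -1000.0:
        raise ValueError("δ values must exceed −1000‰")
    denom = 1000.0 + dw
    eps = ((1000.0 + db) / denom - 1.0) * 1000.0
    # ∂ε/∂δ_BP = 1000/(1000+δ_W); ∂ε/∂δ_W = −1000·(1000+δ_BP)/(1000+δ_W)²
    de_db = 1000.0 / denom
    de_dw = -1000.0 * (1000.0 + db) / denom**2
    sigma = math.hypot(de_db * delta_bp.sigma, de_dw * delta_water.sigma)
    return IsotopeValue(eps, sigma, min(delta_bp.n, delta_water.n))


def delta_bp_from_epsilon(epsilon: float, delta_water: float) -> float:
    """Invert the ε definition: the lipid δ²H implied by ε and water δ²H."""
    if delta_water <= -1000.0:
        raise ValueError("water δ²H must exceed −1000‰")
    return (1.0 + epsilon / 1000.0) * (1000.0 + delta_water) - 1000.0


def weighted_mean(values: Sequence[IsotopeValue], sigma_floor: float = 0.5) -> IsotopeValue:
    """Inverse-variance weighted mean of isotope values.

    Weights are 1/σ² (a σ of zero is replaced by ``sigma_floor`` so
    noise-free synthetic data remains well posed). The reported σ is the
    larger of (a) the weighted standard deviation of the replicates and
    (b) the propagated standard error of the weighted mean — the
    conservative rule used when averaging biological and analytical
    replicates of unequal precision.
    """
    values = list(values)
    if not values:
        raise ValueError("weighted_mean requires at least one value")
    if sigma_floor <= 0:
        raise ValueError("sigma_floor must be > 0")
    if len(values) == 1:
        return values[0]
    x = np.array([v.value for v in values], dtype=float)
    s = np.array([max(v.sigma, sigma_floor) for v in values], dtype=float)
    w = 1.0 / s**2
    wsum = w.sum()
    mean = float(np.sum(w * x) / wsum)
    sigma_prop = float(1.0 / math.sqrt(wsum))
    if len(x) > 1:
        # weighted sample SD with an effective-n bias correction
        neff = wsum**2 / np.sum(w**2)
        var = float(np.sum(w * (x - mean) ** 2) / wsum)
        if neff > 1:
            var *= neff / (neff - 1.0)
        sigma_rep = math.sqrt(var)
    else:  # pragma: no cover - handled by early return
        sigma_rep = 0.0
    n = int(sum(v.n for v in values))
    return IsotopeValue(mean, max(sigma_rep, sigma_prop), n)


def abundance_weighted_mean(
    profile: BiphytaneProfile | Mapping[int, float],
    per_moiety: Mapping[int, IsotopeValue],
    threshold: float = ABUNDANCE_THRESHOLD,
) -> IsotopeValue:
    """Abundance-weighted mean of per-moiety values with the >5 % rule.

    Moieties whose relative abundance (over all detected moieties) is at
    or below ``threshold``, or which have no measured value, are excluded;
    the remaining abundances are renormalized before weighting. σ is
    propagated through the fixed renormalized weights (abundance
    uncertainty is not modelled here).
    """
    abundances = (
        profile.abundances if isinstance(profile, BiphytaneProfile) else dict(profile)
    )
    included = {
        ring: ab
        for ring, ab in abundances.items()
        if ab > threshold and ring in per_moiety and per_moiety[ring] is not None
    }
    excluded = sorted(set(abundances) - set(included))
    if excluded:
        warnings.warn(
            f"moieties excluded from abundance-weighted mean "
            f"(≤{threshold:.0%} or no value): BP-{', BP-'.join(map(str, excluded))}",
            stacklevel=2,
        )
    if not included:
        raise BpisoError(
            "no moiety passes the abundance threshold with a measured value"
        )
    total = sum(included.values())
    mean = 0.0
    var = 0.0
    n = 0
    for ring, ab in included.items():
        w = ab / total
        v = per_moiety[ring]
        mean += w * v.value
        var += (w * v.sigma) ** 2
        n += v.n
    return IsotopeValue(mean, math.sqrt(var), n)


def _ring_index(abundances: Sequence[float], max_ring: int) -> float:
    a = np.asarray(abundances, dtype=float)
    if a.size != max_ring + 1:
        raise ValueError(f"expected {max_ring + 1} abundances, got {a.size}")
    if np.any(a < 0):
        raise ValueError("abundances must be non-negative")
    total = a.sum()
    if total <= 0:
        raise ValueError("abundance vector must not be all zero")
    rings = np.arange(max_ring + 1, dtype=float)
    return float(np.sum(rings * a) / total)


def ring_index_bp(abundances: Sequence[float]) -> float:
    """Biphytane Ring Index from the (BP-0, BP-1, BP-2, BP-3) abundances.

    RI_BP = (BP-1 + 2·BP-2 + 3·BP-3) / Σ BP, in [0, 3]. The vector is
    normalized internally, so any positive rescaling gives the same RI.
    """
    return _ring_index(abundances, max_ring=3)


def ring_index_gdgt(abundances: Sequence[float]) -> float:
    """iGDGT Ring Index from the (iGDGT-0 .. iGDGT-8) abundances, in [0, 8]."""
    return _ring_index(abundances, max_ring=8)


def ring_difference(
    eps_by_moiety: Mapping[int, IsotopeValue]
) -> dict[int, IsotopeValue]:
    """Per-moiety ring difference Δε/ring (‰ per ring).

    For each moiety X > 0 with a value, Δε/ring(X) is the unweighted mean
    over all lower-ring moieties Y < X (with values) of
    (ε_X − ε_Y)/(X − Y). BP-0 is reported as 0 by definition. σ is
    propagated per pair and combined in quadrature through the mean.
    """
    rings = sorted(r for r, v in eps_by_moiety.items() if v is not None)
    if len(rings) < 2:
        warnings.warn("fewer than two moieties with ε values; no ring differences")
        return {}
    out: dict[int, IsotopeValue] = {}
    if rings[0] == 0:
        out[0] = IsotopeValue(0.0, 0.0, eps_by_moiety[0].n)
    for x in rings:
        lower = [y for y in rings if y < x]
        if not lower:
            continue
        pair_vals = []
        pair_vars = []
        for y in lower:
            ex, ey = eps_by_moiety[x], eps_by_moiety[y]
            span = x - y
            pair_vals.append((ex.value - ey.value) / span)
            pair_vars.append((ex.sigma**2 + ey.sigma**2) / span**2)
        m = len(pair_vals)
        val = float(np.mean(pair_vals))
        sigma = math.sqrt(sum(pair_vars)) / m
        out[x] = IsotopeValue(val, sigma, eps_by_moiety[x].n)
    return out


def ring_epsilon_slope(eps_by_moiety: Mapping[int, IsotopeValue]) -> IsotopeValue:
    """Mean per-ring enrichment: OLS slope of ε on ring number (‰/ring).

    The single-number "mean ring difference" summarizing a treatment is
    the ordinary least-squares slope of the per-moiety ²ε_L/W values
    against ring number, over the moieties with measured values. With
    only two moieties this reduces to their pairwise Δε/ring.
    """
    pts = sorted((r, v) for r, v in eps_by_moiety.items() if v is not None)
    if len(pts) < 2:
        raise ValueError("need ε for at least two moieties to fit a ring slope")
    r = np.array([p[0] for p in pts], dtype=float)
    e = np.array([p[1].value for p in pts], dtype=float)
    rbar, ebar = r.mean(), e.mean()
    sxx = float(np.sum((r - rbar) ** 2))
    slope = float(np.sum((r - rbar) * (e - ebar)) / sxx)
    # first-order σ from the per-moiety ε uncertainties through the OLS weights
    coef = (r - rbar) / sxx
    sigma = math.sqrt(float(np.sum((coef * [p[1].sigma for p in pts]) ** 2)))
    n = min(p[1].n for p in pts)
    return IsotopeValue(slope, sigma, n)
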