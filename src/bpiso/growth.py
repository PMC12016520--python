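"""Specific growth rate from OD600 time series and doubling time.

μ is the slope of ln(OD600) on time over the early-to-mid exponential
window; T_D = ln(2)/μ. Chemostat cultures do not satisfy this relation
(their doubling time is set by the dilution rate), so the pipeline routes
them around this module via a metadata flag.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats

from .datatypes import GrowthCurve, RateEstimate
from .exceptions import FittingError

__all__ = ["fit_growth_rate", "doubling_time", "DEFAULT_WINDOW"]

#: default exponential-phase window: points where OD600 lies between 5%
#: and 60% of the curve's maximum
DEFAULT_WINDOW = (0.05, 0.60)


def doubling_time(mu: float) -> float:
    """Doubling time T_D = ln(2)/μ in hours, for μ > 0 (h⁻¹)."""
    if mu <= 0:
        raise ValueError(f"doubling time undefined for mu = {mu} <= 0")
    return math.log(2.0) / mu


def fit_growth_rate(
    curve: GrowthCurve, window: tuple[float, float] = DEFAULT_WINDOW
) -> RateEstimate:
    """OLS fit of ln(OD600) on time over the exponential-phase window.

    ``window`` is an (low, high) pair of OD fractions of the curve's
    maximum; points whose OD falls inside it are used. At least three
    positive-OD points are required.
    """
    lo_frac, hi_frac = window
    if not (0 <= lo_frac < hi_frac):
        raise ValueError(f"invalid window {window}")
    od = curve.od600
    t = curve.times
    od_max = float(np.nanmax(od))
    mask = (od >= lo_frac * od_max) & (od <= hi_frac * od_max)
    # constant curves: the whole series is "the window"
    if od_max > 0 and np.allclose(od, od_max):
        mask = np.ones_like(od, dtype=bool)
    if np.any(mask & (od <= 0)):
        raise FittingError(
            f"non-positive OD600 inside the fitting window for {curve.culture_id}"
        )
    n = int(mask.sum())
    if n < 3:
        raise FittingError(
            f"fewer than 3 points in the exponential window for {curve.culture_id} "
            f"(window {window}, {n} usable)"
        )
    tw = t[mask]
    yw = np.log(od[mask])
    res = stats.linregress(tw, yw)
    mu = float(res.slope)
    mu_se = float(res.stderr) if np.isfinite(res.stderr) else 0.0
    r2 = float(res.rvalue**2) if np.isfinite(res.rvalue) else 1.0
    td = doubling_time(mu) if mu > 0 else float("inf")
    idx = np.flatnonzero(mask)
    return RateEstimate(
        culture_id=curve.culture_id,
        mu=mu,
        mu_se=mu_se,
        doubling_time=td,
        window=(int(idx[0]), int(idx[-1])),
        r_squared=r2,
        n_points=n,
    )
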