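"""Core value objects shared across the pipeline.

All isotope values are expressed in permil (‰) on the VSMOW scale unless a
field name says otherwise (``d2H_raw`` is relative to the working H2
reference gas). Uncertainties are 1-sigma standard deviations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "IsotopeValue",
    "PeakMeasurement",
    "StandardDefinition",
    "CalibrationFit",
    "BiphytaneProfile",
    "GrowthCurve",
    "RateEstimate",
    "TreatmentResult",
]


@dataclass(frozen=True)
class IsotopeValue:
    """A δ or ε value in ‰ with its 1σ uncertainty and replicate count.

    Parameters
    ----------
    value : float
        The isotope value in ‰.
    sigma : float
        1σ uncertainty in ‰; must be non-negative.
    n : int
        Number of contributing measurements (>= 1).
    """

    value: float
    sigma: float = 0.0
    n: int = 1

    def __post_init__(self) -> None:
        if not np.isfinite(self.value):
            raise ValueError(f"isotope value must be finite, got {self.value}")
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.value:.1f} ± {self.sigma:.1f}‰ (n={self.n})"


@dataclass
class PeakMeasurement:
    """One integrated chromatographic peak from a GC-P-IRMS run."""

    run_id: str
    injection: int
    compound: str
    amplitude: float  # peak amplitude (mV) or area, > 0
    d2H_raw: float  # ‰ vs H2 reference gas
    is_standard: bool = False
    rt_s: float = float("nan")
    area_Vs: float = float("nan")
    sample_id: Optional[str] = None
    treatment: Optional[str] = None
    replicate: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.compound:
            raise ValueError("compound label must be non-empty")
        if not (self.amplitude > 0):
            raise ValueError(
                f"peak amplitude must be > 0, got {self.amplitude} "
                f"({self.run_id}/{self.compound})"
            )


@dataclass(frozen=True)
class StandardDefinition:
    """Accepted δ²H of a co-run standard compound on the VSMOW scale."""

    compound: str
    accepted_d2H: float  # ‰ VSMOW
    accepted_sigma: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.accepted_d2H):
            raise ValueError(f"accepted δ²H for {self.compound} must be finite")


@dataclass
class CalibrationFit:
    """Fitted standards regression: raw δ²H as response on accepted δ²H.

    ``coefficients`` are ordered (offset, scale[, size, size×accepted])
    depending on which size-effect terms were enabled. ``covariance`` is
    the coefficient covariance matrix in the same order.
    """

    coefficients: np.ndarray
    covariance: np.ndarray
    residual_rmse: float
    n_standards: int
    terms: tuple[str, ...]
    amplitude_range: tuple[float, float]
    repeatability: "object" = None  # AmplitudeRepeatability, set by fit

    @property
    def offset(self) -> float:
        return float(self.coefficients[0])

    @property
    def scale(self) -> float:
        return float(self.coefficients[1])

    def __post_init__(self) -> None:
        k = len(self.coefficients)
        cov = np.asarray(self.covariance, dtype=float)
        if cov.shape != (k, k):
            raise ValueError("covariance shape does not match coefficients")
        if not np.allclose(cov, cov.T, atol=1e-8):
            raise ValueError("covariance must be symmetric")
        if self.n_standards < k + 1:
            raise ValueError(
                f"need at least {k + 1} standards for {k} coefficients, "
                f"got {self.n_standards}"
            )


#: ring numbers carried by the four biphytane moieties
BP_RINGS = (0, 1, 2, 3)


@dataclass
class BiphytaneProfile:
    """Per-moiety relative abundances and calibrated δ²H for one sample.

    ``abundances`` maps ring number (0..3) to relative abundance of that
    biphytane; ``d2H`` maps ring number to a calibrated
    :class:`IsotopeValue`, with missing entries meaning the moiety was
    below detection ("n.d.").
    """

    sample_id: str
    abundances: dict[int, float]
    d2H: dict[int, IsotopeValue] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for ring in self.abundances:
            if ring not in BP_RINGS:
                raise ValueError(f"unknown biphytane ring number {ring}")
        vals = np.array(list(self.abundances.values()), dtype=float)
        if np.any(vals < 0) or np.any(vals > 1):
            raise ValueError("relative abundances must lie in [0, 1]")
        if vals.size and abs(vals.sum() - 1.0) > 1e-6:
            raise ValueError(
                f"abundances must sum to 1 within 1e-6, got {vals.sum():.8f} "
                f"for sample {self.sample_id}"
            )


@dataclass
class GrowthCurve:
    """An OD600 time series for one culture."""

    culture_id: str
    times: np.ndarray  # hours
    od600: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.od600 = np.asarray(self.od600, dtype=float)
        if self.times.shape != self.od600.shape:
            raise ValueError("times and od600 must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError(f"times must be strictly increasing ({self.culture_id})")
        if np.any(self.times < 0):
            raise ValueError(f"negative times in growth curve {self.culture_id}")


@dataclass
class RateEstimate:
    """Specific growth rate μ (h⁻¹) and doubling time T_D = ln2/μ."""

    culture_id: str
    mu: float
    mu_se: float
    doubling_time: float
    window: tuple[int, int]
    r_squared: float
    n_points: int

    def __post_init__(self) -> None:
        if self.mu_se < 0:
            raise ValueError("mu_se must be >= 0")


@dataclass
class TreatmentResult:
    """Reduced isotope results for one experimental treatment."""

    treatment: str
    experiment: str
    level: float
    water_delta: IsotopeValue
    abundances: dict[int, float]
    epsilon: dict[int, IsotopeValue]  # per-moiety ²ε_L/W
    d2H: dict[int, IsotopeValue]  # per-moiety calibrated δ²H_BP
    ring_difference: dict[int, IsotopeValue]  # per-moiety Δε/ring (mean pairwise)
    weighted_d2H: IsotopeValue
    weighted_epsilon: IsotopeValue
    mean_ring_difference: IsotopeValue  # slope of ε on ring number
    ring_index: float
    doubling_time: Optional[float] = None
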