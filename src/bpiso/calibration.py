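"""GC-P-IRMS standards calibration and the hydrogenation correction.

Raw δ²H measured against the H2 working gas is placed on the VSMOW scale
with co-run n-alkane standards. The regression is run in the "inverted"
(errors-in-calibration) orientation — raw value as response on accepted
value — and then solved for the accepted-scale value of each unknown:

    d2H_raw = β0 + β1·accepted + β2·A + β3·accepted·A

β0 is the instrument offset, β1 the scale compression, and the optional
amplitude terms (β2, β3) remove peak-size (linearity) effects. Per-peak
1σ combines the regression prediction uncertainty (via the coefficient
covariance, delta method) with an amplitude-dependent repeatability floor
estimated from replicate standards, so small peaks carry larger errors.

The hydrogenation correction removes the isotope dilution caused by the
hydrogens chemically added when alkyl iodides are reduced to biphytanes,
by pool mass balance over the molecule's H inventory.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .datatypes import CalibrationFit, IsotopeValue, PeakMeasurement, StandardDefinition
from .exceptions import CalibrationError

__all__ = [
    "fit_calibration",
    "apply_calibration",
    "hydrogenation_correct",
    "calibration_diagnostics",
    "AmplitudeRepeatability",
    "CalibrationDiagnostics",
    "HYDROGENATION_N_TOTAL",
    "HYDROGENATION_N_ADDED",
]

#: biphytane C40H82: total H per molecule, and H added during
#: hydrogenation (one at each cleaved ether terminus)
HYDROGENATION_N_TOTAL = 82
HYDROGENATION_N_ADDED = 2


@dataclass
class AmplitudeRepeatability:
    """Amplitude-dependent repeatability of standard residuals.

    The standards' residuals are binned by amplitude quantile, each bin's
    RMS is computed, and the IRMS shot-noise shape σ(A) = a + b/A (a, b
    >= 0) is fitted through the bins. Lookup evaluates that law, so the
    repeatability floor decreases smoothly (never increases) with peak
    size.
    """

    base: float  # a, ‰
    inverse_coeff: float  # b, ‰·amplitude

    @classmethod
    def from_residuals(
        cls, amplitudes: np.ndarray, residuals: np.ndarray, n_bins: int = 4
    ) -> "AmplitudeRepeatability":
        amplitudes = np.asarray(amplitudes, dtype=float)
        residuals = np.asarray(residuals, dtype=float)
        n_bins = max(1, min(n_bins, len(amplitudes) // 3 or 1))
        qs = np.quantile(amplitudes, np.linspace(0, 1, n_bins + 1))
        qs[-1] += 1e-9
        centers, rms = [], []
        for lo, hi in zip(qs[:-1], qs[1:]):
            mask = (amplitudes >= lo) & (amplitudes < hi)
            if mask.sum() == 0:
                continue
            centers.append(float(amplitudes[mask].mean()))
            rms.append(float(np.sqrt(np.mean(residuals[mask] ** 2))))
        centers = np.array(centers)
        rms = np.array(rms)
        if centers.size < 2:
            return cls(base=float(rms.mean()) if rms.size else 0.0, inverse_coeff=0.0)
        X = np.column_stack([np.ones_like(centers), 1.0 / centers])
        coef, _, _, _ = np.linalg.lstsq(X, rms, rcond=None)
        a, b = float(coef[0]), float(coef[1])
        if a < 0 or b < 0:  # degenerate fit: fall back to a flat floor
            return cls(base=float(np.sqrt(np.mean(rms**2))), inverse_coeff=0.0)
        return cls(base=a, inverse_coeff=b)

    def __call__(self, amplitude: float) -> float:
        return self.base + self.inverse_coeff / max(amplitude, 1e-9)


def _design_matrix(
    accepted: np.ndarray, amplitude: np.ndarray, terms: tuple[str, ...]
) -> np.ndarray:
    cols = [np.ones_like(accepted), accepted]
    if "size" in terms:
        cols.append(amplitude)
    if "size_x_accepted" in terms:
        cols.append(amplitude * accepted)
    return np.column_stack(cols)


def fit_calibration(
    standards: Sequence[PeakMeasurement],
    defs: Iterable[StandardDefinition],
    size_term: bool = True,
    interaction_term: bool = False,
    robust_refit: bool = False,
) -> CalibrationFit:
    """Fit the inverted standards regression.

    Parameters
    ----------
    standards : peak measurements flagged as standards.
    defs : accepted VSMOW values, matched to peaks by compound label.
    size_term, interaction_term : include the amplitude covariate and/or
        its interaction with the accepted value (peak-size correction).
    robust_refit : drop standards with \\|studentized residual\\| > 4 and
        refit once (off by default; logged via a warning when it fires).
    """
    standards = list(standards)
    accepted_map = {d.compound: d.accepted_d2H for d in defs}
    for p in standards:
        if p.compound not in accepted_map:
            raise CalibrationError(
                f"standard peak compound {p.compound!r} has no accepted value"
            )
    if not standards:
        raise CalibrationError("no standard peaks supplied")
    accepted = np.array([accepted_map[p.compound] for p in standards])
    raw = np.array([p.d2H_raw for p in standards])
    amp = np.array([p.amplitude for p in standards])
    if np.unique(accepted).size < 2:
        raise CalibrationError("need >= 2 distinct accepted values to calibrate")
    terms: tuple[str, ...] = ("offset", "scale")
    if size_term:
        if np.unique(amp).size < 2:
            raise CalibrationError(
                "size terms enabled but all standard amplitudes are identical"
            )
        terms += ("size",)
    if interaction_term:
        terms += ("size_x_accepted",)

    def _ols(acc, raw_, amp_):
        X = _design_matrix(acc, amp_, terms)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise CalibrationError("rank-deficient standards design")
        beta, _, _, _ = np.linalg.lstsq(X, raw_, rcond=None)
        resid = raw_ - X @ beta
        dof = max(len(raw_) - X.shape[1], 1)
        s2 = float(resid @ resid) / dof
        XtX_inv = np.linalg.inv(X.T @ X)
        return X, beta, resid, s2 * XtX_inv, math.sqrt(float(np.mean(resid**2)))

    X, beta, resid, cov, rmse = _ols(accepted, raw, amp)
    if robust_refit and len(standards) > X.shape[1] + 1:
        s = math.sqrt(max(float(resid @ resid) / (len(raw) - X.shape[1]), 1e-30))
        hat = np.einsum("ij,jk,ik->i", X, np.linalg.inv(X.T @ X), X)
        stud = resid / (s * np.sqrt(np.clip(1.0 - hat, 1e-12, None)))
        keep = np.abs(stud) <= 4.0
        if not keep.all():
            warnings.warn(
                f"robust refit dropped {int((~keep).sum())} standard peak(s) "
                f"with |studentized residual| > 4"
            )
            X, beta, resid, cov, rmse = _ols(accepted[keep], raw[keep], amp[keep])
            standards = [p for p, k in zip(standards, keep) if k]
            amp = amp[keep]

    fit = CalibrationFit(
        coefficients=beta,
        covariance=cov,
        residual_rmse=rmse,
        n_standards=len(standards),
        terms=terms,
        amplitude_range=(float(amp.min()), float(amp.max())),
    )
    fit.repeatability = AmplitudeRepeatability.from_residuals(amp, resid)
    return fit


def _effective_scale_and_intercept(
    fit: CalibrationFit, amplitude: float
) -> tuple[float, float, np.ndarray]:
    """At fixed amplitude A the model is raw = b + m·accepted; return
    (m, b) and the gradient layout used for σ propagation."""
    beta = fit.coefficients
    idx = {t: i for i, t in enumerate(fit.terms)}
    b = beta[idx["offset"]]
    m = beta[idx["scale"]]
    if "size" in idx:
        b = b + beta[idx["size"]] * amplitude
    if "size_x_accepted" in idx:
        m = m + beta[idx["size_x_accepted"]] * amplitude
    return float(m), float(b), beta


def apply_calibration(
    fit: CalibrationFit,
    peaks: Sequence[PeakMeasurement],
    amplitude_tolerance: float = 2.0,
) -> list[IsotopeValue]:
    """Invert the standards regression to put peaks on the VSMOW scale.

    Solves accepted = (raw − b(A)) / m(A) per peak. σ combines the
    delta-method prediction uncertainty from the coefficient covariance
    with the amplitude-binned repeatability of the standards. Peaks whose
    amplitude falls outside ``amplitude_tolerance`` times the standards'
    amplitude range trigger an extrapolation warning.
    """
    lo, hi = fit.amplitude_range
    span = max(hi - lo, 1e-12)
    out: list[IsotopeValue] = []
    idx = {t: i for i, t in enumerate(fit.terms)}
    for p in peaks:
        m, b, beta = _effective_scale_and_intercept(fit, p.amplitude)
        if abs(m) < 1e-8:
            raise CalibrationError(
                "calibration scale is ~0 at this amplitude; cannot invert"
            )
        if p.amplitude < lo - amplitude_tolerance * span or p.amplitude > (
            hi + amplitude_tolerance * span
        ):
            warnings.warn(
                f"peak {p.run_id}/{p.compound} amplitude {p.amplitude:.0f} "
                f"extrapolates beyond the standards' range [{lo:.0f}, {hi:.0f}]"
            )
        value = (p.d2H_raw - b) / m
        # gradient of value wrt coefficients, in fit.terms order
        grad = np.zeros_like(beta)
        grad[idx["offset"]] = -1.0 / m
        grad[idx["scale"]] = -value / m
        if "size" in idx:
            grad[idx["size"]] = -p.amplitude / m
        if "size_x_accepted" in idx:
            grad[idx["size_x_accepted"]] = -p.amplitude * value / m
        var_pred = float(grad @ fit.covariance @ grad)
        rep = fit.repeatability(p.amplitude) if fit.repeatability else 0.0
        sigma = math.sqrt(max(var_pred, 0.0) + (rep / abs(m)) ** 2)
        out.append(IsotopeValue(value, sigma, 1))
    return out


def hydrogenation_correct(
    measured: IsotopeValue,
    delta_added: IsotopeValue,
    n_added: int = HYDROGENATION_N_ADDED,
    n_total: int = HYDROGENATION_N_TOTAL,
) -> IsotopeValue:
    """Remove the isotope dilution from hydrogenation by H-pool mass balance.

    The measured biphytane carries ``n_total`` hydrogens of which
    ``n_added`` were introduced (at δ²H ``delta_added``) when the ether
    bonds were cleaved and reduced; the biosynthetic signal is

        δ_corr = (n_total·δ_meas − n_added·δ_added) / (n_total − n_added)

    σ is propagated in quadrature with the same weights. The returned
    value's ``correction`` attribute records δ_corr − δ_meas in ‰.
    """
    if n_added < 0 or n_added >= n_total:
        raise ValueError(f"need 0 <= n_added < n_total, got {n_added}/{n_total}")
    if n_added == 0:
        return measured
    n_bio = n_total - n_added
    corrected = (n_total * measured.value - n_added * delta_added.value) / n_bio
    sigma = math.hypot(
        (n_total / n_bio) * measured.sigma, (n_added / n_bio) * delta_added.sigma
    )
    result = IsotopeValue(corrected, sigma, measured.n)
    object.__setattr__(result, "correction", corrected - measured.value)
    return result


@dataclass
class CalibrationDiagnostics:
    """Per-standard residuals and summary diagnostics of a calibration."""

    compounds: list[str]
    residuals: np.ndarray  # ‰, raw − fitted
    leverages: np.ndarray
    residual_rmse: float
    high_leverage: list[str]

    def to_records(self) -> list[dict]:
        return [
            {
                "compound": c,
                "residual_permil": float(r),
                "leverage": float(h),
            }
            for c, r, h in zip(self.compounds, self.residuals, self.leverages)
        ]


def calibration_diagnostics(
    fit: CalibrationFit,
    standards: Sequence[PeakMeasurement],
    defs: Iterable[StandardDefinition],
) -> CalibrationDiagnostics:
    """Residuals and leverage flags for the standards under ``fit``."""
    accepted_map = {d.compound: d.accepted_d2H for d in defs}
    accepted = np.array([accepted_map[p.compound] for p in standards])
    raw = np.array([p.d2H_raw for p in standards])
    amp = np.array([p.amplitude for p in standards])
    X = _design_matrix(accepted, amp, fit.terms)
    resid = raw - X @ fit.coefficients
    hat = np.einsum("ij,jk,ik->i", X, np.linalg.pinv(X.T @ X), X)
    k = X.shape[1]
    thresh = 2.0 * k / max(len(standards), 1)
    flagged = [p.compound for p, h in zip(standards, hat) if h > thresh]
    return CalibrationDiagnostics(
        compounds=[p.compound for p in standards],
        residuals=resid,
        leverages=hat,
        residual_rmse=math.sqrt(float(np.mean(resid**2))),
        high_leverage=flagged,
    )
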