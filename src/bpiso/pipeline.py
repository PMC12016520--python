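"""End-to-end data reduction: calibrate → correct → ε → weights → RI →
Δε/ring → summaries.

The pipeline consumes the four delimited tables (standards peaks, sample
peaks, per-culture metadata, growth series), reduces them to per-
treatment results, and writes a machine-readable bundle: delimited
result tables, a JSON run summary, and a plain-text report. Every number
in the report is taken from a table cell; rendering only rounds.

Reduction order (logged per run): the standards regression is fitted
once over all standards peaks; sample peaks are calibrated and
hydrogenation-corrected; injections are averaged per culture and moiety
by inverse-variance weighting; ²ε_L/W is computed per culture from that
culture's own water δ²H; cultures are then combined per treatment by
weighted mean. Relative abundances come from peak areas within each
injection. Chemostat cultures take their doubling time from the set
dilution time in the metadata instead of a growth-curve fit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calibration import (
    apply_calibration,
    calibration_diagnostics,
    fit_calibration,
    hydrogenation_correct,
)
from .datatypes import (
    BiphytaneProfile,
    IsotopeValue,
    PeakMeasurement,
    TreatmentResult,
)
from .exceptions import BpisoError, ConfigError
from .fractionation import (
    abundance_weighted_mean,
    epsilon_lw,
    ring_difference,
    ring_epsilon_slope,
    ring_index_bp,
    weighted_mean,
)
from .growth import DEFAULT_WINDOW, fit_growth_rate
from .io import read_growth, read_metadata, read_peak_table, read_standard_definitions
from .stats import summarize_experiment

__all__ = ["PipelineConfig", "ResultsBundle", "run_pipeline", "reduce_dataset"]


@dataclass
class PipelineConfig:
    """Paths and decision knobs of one reduction run."""

    standards_path: str
    samples_path: str
    metadata_path: str
    growth_path: str
    standard_defs_path: str
    out_dir: Optional[str] = None
    size_term: bool = True
    interaction_term: bool = False
    robust_refit: bool = False
    n_total_h: int = 82
    n_added_h: int = 2
    delta_added: float = -720.0  # ‰, δ²H of hydrogenation hydrogen
    delta_added_sigma: float = 0.0
    abundance_threshold: float = 0.05
    growth_window: tuple[float, float] = DEFAULT_WINDOW
    water_sigma_default: float = 0.5  # ‰, media-water analytical precision
    sigma_floor: float = 0.5  # ‰, replaces zero σ in weighted means
    seed: int = 0

    def validate(self) -> "PipelineConfig":
        if not (0 <= self.abundance_threshold < 0.5):
            raise ConfigError("abundance_threshold must be in [0, 0.5)")
        if not (0 <= self.n_added_h < self.n_total_h):
            raise ConfigError("need 0 <= n_added_h < n_total_h")
        for name in ("standards_path", "samples_path", "metadata_path",
                     "growth_path", "standard_defs_path"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise ConfigError(f"{name} does not exist: {p}")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "growth_window" in raw and isinstance(raw["growth_window"], list):
            raw["growth_window"] = tuple(raw["growth_window"])
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class ResultsBundle:
    """Everything a reduction run produces."""

    treatment_results: list[TreatmentResult]
    per_culture: pd.DataFrame
    per_treatment: pd.DataFrame
    growth_rates: pd.DataFrame
    calibration: dict
    summaries: dict
    log: list[str] = field(default_factory=list)

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "per_culture": out / "per_culture.tsv",
            "per_treatment": out / "per_treatment.tsv",
            "growth_rates": out / "growth_rates.tsv",
            "summary": out / "run_summary.json",
            "report": out / "report.txt",
            "log": out / "run_log.txt",
        }
        self.per_culture.to_csv(paths["per_culture"], sep="\t", index=False)
        self.per_treatment.to_csv(paths["per_treatment"], sep="\t", index=False)
        self.growth_rates.to_csv(paths["growth_rates"], sep="\t", index=False)
        payload = {"calibration": self.calibration, "summaries": self.summaries}
        paths["summary"].write_text(json.dumps(payload, indent=2, sort_keys=True))
        paths["report"].write_text(self.render_report())
        paths["log"].write_text("\n".join(self.log) + "\n")
        return paths

    def render_report(self) -> str:
        """Plain-text report mirroring the per-treatment result tables.

        δ and ε render as integer ‰, RI and abundances to 2 decimals;
        full precision stays in the TSV tables.
        """
        lines = ["Per-treatment biphytane H-isotope results", "=" * 60]
        for r in self.treatment_results:
            lines.append(
                f"{r.experiment} / {r.treatment} (level {r.level:g}): "
                f"water δ²H = {r.water_delta.value:.1f}‰"
            )
            for ring in sorted(r.epsilon):
                e = r.epsilon[ring]
                d = r.d2H[ring]
                rd = r.ring_difference.get(ring)
                rd_s = f"{rd.value:7.0f}" if rd is not None else "   n.d."
                lines.append(
                    f"  BP-{ring}: abundance {r.abundances.get(ring, 0):.2f}  "
                    f"δ²H {d.value:5.0f} ±{d.sigma:3.0f}  "
                    f"ε {e.value:5.0f} ±{e.sigma:3.0f}  Δε/ring {rd_s}"
                )
            lines.append(
                f"  weighted: δ²H {r.weighted_d2H.value:.0f}‰, "
                f"ε {r.weighted_epsilon.value:.0f}‰, "
                f"mean Δε/ring {r.mean_ring_difference.value:.1f}‰/ring, "
                f"RI {r.ring_index:.2f}"
            )
        lines.append("")
        for name, s in self.summaries.items():
            lines.append(f"{name}: " + json.dumps(s, sort_keys=True))
        return "\n".join(lines) + "\n"


def _relative_abundances(peaks: list[PeakMeasurement]) -> dict[int, float]:
    """Mean relative area per moiety over a sample's injections."""
    by_inj: dict[int, dict[int, float]] = {}
    for p in peaks:
        ring = int(p.compound.split("-")[1])
        by_inj.setdefault(p.injection, {})[ring] = p.area_Vs
    acc: dict[int, list[float]] = {}
    for areas in by_inj.values():
        total = sum(areas.values())
        for ring, a in areas.items():
            acc.setdefault(ring, []).append(a / total)
    return {ring: float(np.mean(v)) for ring, v in sorted(acc.items())}


def reduce_dataset(
    standards: list[PeakMeasurement],
    samples: list[PeakMeasurement],
    standard_defs,
    metadata: pd.DataFrame,
    growth_curves: dict,
    config: PipelineConfig,
) -> ResultsBundle:
    """Reduce in-memory peak tables to per-treatment results."""
    log = [f"bpiso {__version__}", f"config_hash {config.config_hash()}",
           f"seed {config.seed}"]
    # --- calibration -----------------------------------------------------
    fit = fit_calibration(
        standards,
        standard_defs,
        size_term=config.size_term,
        interaction_term=config.interaction_term,
        robust_refit=config.robust_refit,
    )
    diag = calibration_diagnostics(fit, standards, standard_defs)
    log.append(
        f"calibration: terms={fit.terms} offset={fit.offset:.3f}‰ "
        f"scale={fit.scale:.5f} rmse={fit.residual_rmse:.3f}‰ "
        f"n={fit.n_standards}"
    )
    # --- per-culture reduction -------------------------------------------
    meta = metadata.set_index("culture_id")
    delta_added = IsotopeValue(
        config.delta_added, config.delta_added_sigma, 1
    )
    by_sample: dict[str, list[PeakMeasurement]] = {}
    for p in samples:
        if p.sample_id is None:
            raise BpisoError(f"sample peak without sample_id in run {p.run_id}")
        by_sample.setdefault(p.sample_id, []).append(p)

    culture_rows = []
    profiles: dict[str, BiphytaneProfile] = {}
    culture_eps: dict[str, dict[int, IsotopeValue]] = {}
    culture_d2h: dict[str, dict[int, IsotopeValue]] = {}
    for culture, peaks in by_sample.items():
        if culture not in meta.index:
            raise BpisoError(f"reduction failed at metadata lookup: {culture}")
        water = IsotopeValue(
            float(meta.at[culture, "d2h_water_permil"]),
            float(meta.at[culture, "d2h_water_sd"])
            if "d2h_water_sd" in meta.columns
            and np.isfinite(meta.at[culture, "d2h_water_sd"])
            else config.water_sigma_default,
        )
        cal = apply_calibration(fit, peaks)
        corrected = [
            hydrogenation_correct(v, delta_added, config.n_added_h, config.n_total_h)
            for v in cal
        ]
        per_moiety_vals: dict[int, list[IsotopeValue]] = {}
        per_moiety_corr: dict[int, list[float]] = {}
        for p, v in zip(peaks, corrected):
            ring = int(p.compound.split("-")[1])
            per_moiety_vals.setdefault(ring, []).append(v)
            per_moiety_corr.setdefault(ring, []).append(
                getattr(v, "correction", 0.0)
            )
        d2h = {
            ring: weighted_mean(vals, sigma_floor=config.sigma_floor)
            for ring, vals in sorted(per_moiety_vals.items())
        }
        eps = {ring: epsilon_lw(v, water) for ring, v in d2h.items()}
        abund = _relative_abundances(peaks)
        total = sum(abund.values())
        abund = {r: a / total for r, a in abund.items()}
        profiles[culture] = BiphytaneProfile(culture, abund, d2h)
        culture_eps[culture] = eps
        culture_d2h[culture] = d2h
        for ring in d2h:
            culture_rows.append(
                {
                    "culture_id": culture,
                    "treatment": meta.at[culture, "treatment"],
                    "ring": ring,
                    "abundance": abund.get(ring, np.nan),
                    "d2H_cal_permil": d2h[ring].value,
                    "d2H_sigma": d2h[ring].sigma,
                    "eps_permil": eps[ring].value,
                    "eps_sigma": eps[ring].sigma,
                    "n_injections": d2h[ring].n,
                    "hydrogenation_correction_permil": float(
                        np.mean(per_moiety_corr[ring])
                    ),
                }
            )
    log.append(f"reduced {len(profiles)} cultures "
               f"(abundance threshold {config.abundance_threshold:.0%}, "
               f"σ floor {config.sigma_floor}‰)")

    # --- growth ----------------------------------------------------------
    growth_rows = []
    for culture, curve in growth_curves.items():
        ctype = (
            str(meta.at[culture, "culture_type"]) if culture in meta.index else "batch"
        )
        if ctype == "chemostat":
            td = float(meta.at[culture, "dilution_td_h"])
            growth_rows.append(
                {
                    "culture_id": culture,
                    "mu_per_h": np.log(2) / td,
                    "mu_se": np.nan,
                    "doubling_time_h": td,
                    "r_squared": np.nan,
                    "source": "chemostat dilution rate",
                }
            )
        else:
            est = fit_growth_rate(curve, window=config.growth_window)
            growth_rows.append(
                {
                    "culture_id": culture,
                    "mu_per_h": est.mu,
                    "mu_se": est.mu_se,
                    "doubling_time_h": est.doubling_time,
                    "r_squared": est.r_squared,
                    "source": f"OD600 fit, window {config.growth_window}",
                }
            )
    growth_df = pd.DataFrame(growth_rows)

    # --- per-treatment aggregation ---------------------------------------
    results: list[TreatmentResult] = []
    rows = []
    for treatment, group in meta.groupby("treatment", sort=False):
        cultures = [c for c in group.index if c in profiles]
        if not cultures:
            continue
        rings = sorted({r for c in cultures for r in culture_eps[c]})
        eps_t: dict[int, IsotopeValue] = {}
        d2h_t: dict[int, IsotopeValue] = {}
        for ring in rings:
            eps_vals = [culture_eps[c][ring] for c in cultures if ring in culture_eps[c]]
            d_vals = [culture_d2h[c][ring] for c in cultures if ring in culture_d2h[c]]
            eps_t[ring] = weighted_mean(eps_vals, sigma_floor=config.sigma_floor)
            d2h_t[ring] = weighted_mean(d_vals, sigma_floor=config.sigma_floor)
        ab_mat = {
            ring: float(np.mean([profiles[c].abundances.get(ring, 0.0) for c in cultures]))
            for ring in range(4)
        }
        total = sum(ab_mat.values())
        ab_mat = {r: a / total for r, a in ab_mat.items()}
        water = IsotopeValue(
            float(group["d2h_water_permil"].mean()), config.water_sigma_default
        )
        rd = ring_difference(eps_t)
        slope = ring_epsilon_slope(eps_t) if len(eps_t) >= 2 else IsotopeValue(0.0)
        w_eps = abundance_weighted_mean(ab_mat, eps_t, config.abundance_threshold)
        w_d2h = abundance_weighted_mean(ab_mat, d2h_t, config.abundance_threshold)
        ri = ring_index_bp([ab_mat.get(r, 0.0) for r in range(4)])
        td_vals = growth_df[growth_df["culture_id"].isin(cultures)]["doubling_time_h"]
        result = TreatmentResult(
            treatment=str(treatment),
            experiment=str(group["experiment"].iloc[0]),
            level=float(group["level"].iloc[0]),
            water_delta=water,
            abundances=ab_mat,
            epsilon=eps_t,
            d2H=d2h_t,
            ring_difference=rd,
            weighted_d2H=w_d2h,
            weighted_epsilon=w_eps,
            mean_ring_difference=slope,
            ring_index=ri,
            doubling_time=float(td_vals.mean()) if len(td_vals) else None,
        )
        results.append(result)
        row = {
            "experiment": result.experiment,
            "treatment": result.treatment,
            "level": result.level,
            "water_d2H_permil": water.value,
            "ring_index": ri,
            "weighted_d2H_permil": w_d2h.value,
            "weighted_d2H_sigma": w_d2h.sigma,
            "weighted_eps_permil": w_eps.value,
            "weighted_eps_sigma": w_eps.sigma,
            "mean_ring_difference_permil": slope.value,
            "doubling_time_h": result.doubling_time,
        }
        for ring in rings:
            row[f"bp{ring}_abundance"] = ab_mat.get(ring, np.nan)
            row[f"bp{ring}_d2H_permil"] = d2h_t[ring].value
            row[f"bp{ring}_eps_permil"] = eps_t[ring].value
            row[f"bp{ring}_eps_sigma"] = eps_t[ring].sigma
            if ring in rd:
                row[f"bp{ring}_dering_permil"] = rd[ring].value
        rows.append(row)
    per_treatment = pd.DataFrame(rows)

    # --- summaries --------------------------------------------------------
    summaries = {}
    for experiment, exp_results in _group_by_experiment(results).items():
        s = summarize_experiment(exp_results, experiment)
        summaries[experiment] = {
            "n_treatments": s.n_treatments,
            "epsilon_range_permil": s.epsilon_range,
            "epsilon_mean_permil": s.epsilon_mean,
            "epsilon_sd_permil": s.epsilon_sd,
            "ri_range": list(s.ri_range),
            "d2h_range_permil": list(s.d2h_range),
            "mean_ring_difference_permil": s.mean_ring_difference,
        }
    calibration_summary = {
        "terms": list(fit.terms),
        "offset_permil": fit.offset,
        "scale": fit.scale,
        "residual_rmse_permil": fit.residual_rmse,
        "n_standards": fit.n_standards,
        "high_leverage_standards": diag.high_leverage,
    }
    return ResultsBundle(
        treatment_results=results,
        per_culture=pd.DataFrame(culture_rows),
        per_treatment=per_treatment,
        growth_rates=growth_df,
        calibration=calibration_summary,
        summaries=summaries,
        log=log,
    )


def _group_by_experiment(results: list[TreatmentResult]) -> dict[str, list[TreatmentResult]]:
    out: dict[str, list[TreatmentResult]] = {}
    for r in results:
        out.setdefault(r.experiment, []).append(r)
    return out


def run_pipeline(config: PipelineConfig) -> ResultsBundle:
    """Run the full reduction from files per ``config``; write outputs if
    ``config.out_dir`` is set. Deterministic given inputs and seed."""
    config.validate()
    standards = read_peak_table(config.standards_path, is_standard=True)
    samples = read_peak_table(config.samples_path, is_standard=False)
    defs = read_standard_definitions(config.standard_defs_path)
    metadata = read_metadata(config.metadata_path)
    curves = read_growth(config.growth_path)
    bundle = reduce_dataset(standards, samples, defs, metadata, curves, config)
    if config.out_dir:
        bundle.write(config.out_dir)
    return bundle
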