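"""Seeded synthetic GC-P-IRMS instrument runs, cultures, and growth curves.

Everything downstream of peak integration can be exercised without real
chromatograms: this module draws biphytane profiles with known ("truth")
lipid/water fractionations, pushes them through a forward model of the
measurement chain, and emits peak tables with the same structure as
exported instrument data.

Forward model, per peak:

1. the true biphytane δ²H follows from the culture's water δ²H and the
   moiety's true ²ε_L/W via the ε definition;
2. hydrogenation dilutes the H pool: n_added hydrogens at delta_added_H
   mix with n_total − n_added biosynthetic hydrogens;
3. the instrument distorts the diluted value with an offset, a scale
   compression, and a linear peak-size (linearity) effect, then adds
   Gaussian noise with σ(A) = noise_base_sigma + noise_amplitude_coeff/A
   — the shot-noise-like shape where small peaks are noisier.

Standards runs use a synthetic 16-compound n-alkane ladder evenly spaced
over −263…−9‰ vs VSMOW (emulating an A7-style mixture; the individual
accepted values are synthetic stand-ins) plus an nC36 alkane at −259.2‰.

Truth tables are returned on a separate attribute (`StudyDataset.truth`)
and written to a separate file so reduction code cannot accidentally
consume them.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .datatypes import GrowthCurve, PeakMeasurement, StandardDefinition
from .exceptions import ConfigError
from .fractionation import delta_bp_from_epsilon

__all__ = [
    "SyntheticConfig",
    "StudyDataset",
    "standard_ladder",
    "generate_standards_run",
    "generate_sample_run",
    "generate_growth_curve",
    "generate_study",
    "write_study",
]


def standard_ladder() -> list[StandardDefinition]:
    """Synthetic n-alkane calibration ladder (nC15..nC30 plus nC36).

    Sixteen alkanes with accepted δ²H evenly spaced from −263‰ to −9‰
    vs VSMOW, plus nC36 at −259.2‰. The span and the nC36 value match
    commonly used reference mixtures; the individual ladder values are
    synthetic.
    """
    values = np.linspace(-263.0, -9.0, 16)
    ladder = [
        StandardDefinition(f"nC{15 + i}", float(v)) for i, v in enumerate(values)
    ]
    ladder.append(StandardDefinition("nC36", -259.2))
    return ladder


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic study generator.

    Defaults emulate the observed structure of a multi-condition
    S. acidocaldarius culture study: ²ε_L/W centred at −204‰ with 12‰
    spread across cultures, a per-ring enrichment of 7.4‰, media-water
    δ²H between −61‰ and −46‰, and mean biphytane relative abundances
    near (13, 30, 49, 7)% for BP-0..BP-3.
    """

    n_treatments: int = 5
    replicates_per_treatment: int = 3
    true_epsilon_mean: float = -204.0  # ‰
    true_epsilon_sd: float = 12.0  # ‰ between-culture spread
    ring_enrichment_per_ring: float = 7.4  # ‰ per cyclopentane ring
    water_delta_range: tuple[float, float] = (-61.0, -46.0)  # ‰
    abundance_dirichlet_params: tuple[float, float, float, float] = (13.0, 30.0, 49.0, 8.0)
    noise_base_sigma: float = 2.0  # ‰
    noise_amplitude_coeff: float = 2000.0  # ‰·mV
    cal_offset: float = 20.0  # ‰
    cal_scale: float = 0.97  # scale compression
    cal_size_coeff: float = 0.002  # ‰ per mV
    delta_added_H: float = -720.0  # ‰, hydrogenation hydrogen
    n_total_h: int = 82
    n_added_h: int = 2
    amplitude_range: tuple[float, float] = (800.0, 8000.0)  # mV, standards
    sample_total_amplitude: float = 9000.0  # mV split across BP peaks
    injections_per_sample: int = 3
    growth_noise_sd: float = 0.01
    mu_range: tuple[float, float] = (0.05, 0.30)  # h⁻¹
    chemostat: bool = False
    seed: int = 0

    def validate(self) -> "SyntheticConfig":
        if self.n_treatments < 1 or self.replicates_per_treatment < 1:
            raise ConfigError("need at least one treatment and one replicate")
        if self.true_epsilon_sd < 0 or self.growth_noise_sd < 0:
            raise ConfigError("spread parameters must be >= 0")
        if self.noise_base_sigma < 0 or self.noise_amplitude_coeff < 0:
            raise ConfigError("noise parameters must be >= 0")
        if not (0.5 < self.cal_scale < 1.5):
            raise ConfigError(
                f"cal_scale must be in (0.5, 1.5), got {self.cal_scale}"
            )
        if len(self.abundance_dirichlet_params) != 4 or any(
            a <= 0 for a in self.abundance_dirichlet_params
        ):
            raise ConfigError("abundance_dirichlet_params must be 4 positive reals")
        if not (0 <= self.n_added_h < self.n_total_h):
            raise ConfigError("need 0 <= n_added_h < n_total_h")
        lo, hi = self.amplitude_range
        if not (0 < lo <= hi):
            raise ConfigError("amplitude_range must be positive and ordered")
        if self.sample_total_amplitude <= 0:
            raise ConfigError("sample_total_amplitude must be > 0")
        w0, w1 = self.water_delta_range
        if w0 > w1:
            raise ConfigError("water_delta_range must be ordered (low, high)")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for key in ("water_delta_range", "abundance_dirichlet_params",
                    "amplitude_range", "mu_range"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw).validate()


@dataclass
class StudyDataset:
    """A full synthetic study: peaks, metadata, growth, and hidden truth."""

    standards_runs: list[PeakMeasurement]
    sample_runs: list[PeakMeasurement]
    water_deltas: dict[str, float]  # culture_id -> ‰
    growth_curves: dict[str, GrowthCurve]
    metadata: pd.DataFrame  # culture_id, experiment, treatment, level, ...
    truth: pd.DataFrame  # recovery-test channel only
    standard_definitions: list[StandardDefinition] = field(default_factory=standard_ladder)

    def __post_init__(self) -> None:
        treatments = set(self.metadata["treatment"])
        for p in self.sample_runs:
            if p.treatment not in treatments:
                raise ValueError(
                    f"sample peak references unknown treatment {p.treatment!r}"
                )
        missing = set(self.metadata["culture_id"]) - set(self.truth["culture_id"])
        if missing:
            raise ValueError(f"truth table missing cultures: {sorted(missing)}")


def _noise_sigma(config: SyntheticConfig, amplitude: float) -> float:
    return config.noise_base_sigma + config.noise_amplitude_coeff / amplitude


def _instrument(
    config: SyntheticConfig, true_value: float, amplitude: float, rng: np.random.Generator
) -> float:
    raw = (
        config.cal_offset
        + config.cal_scale * true_value
        + config.cal_size_coeff * amplitude
    )
    sigma = _noise_sigma(config, amplitude)
    if sigma > 0:
        raw += rng.normal(0.0, sigma)
    return raw


def generate_standards_run(
    config: SyntheticConfig,
    seed: int,
    run_id: str = "std",
    injection: int = 1,
) -> list[PeakMeasurement]:
    """One peak per ladder compound at randomized amplitudes."""
    config.validate()
    rng = np.random.default_rng(seed)
    lo, hi = config.amplitude_range
    peaks = []
    for i, std in enumerate(standard_ladder()):
        amplitude = float(rng.uniform(lo, hi))
        raw = _instrument(config, std.accepted_d2H, amplitude, rng)
        peaks.append(
            PeakMeasurement(
                run_id=run_id,
                injection=injection,
                compound=std.compound,
                amplitude=amplitude,
                rt_s=600.0 + 60.0 * i,
                area_Vs=amplitude * 2e-3,
                d2H_raw=raw,
                is_standard=True,
            )
        )
    return peaks


def dilute_with_added_h(
    true_delta: float, delta_added: float, n_added: int, n_total: int
) -> float:
    """Forward hydrogenation dilution: mix biosynthetic and added H pools."""
    n_bio = n_total - n_added
    return (n_bio * true_delta + n_added * delta_added) / n_total


def generate_sample_run(
    true_epsilon: dict[int, float],
    abundances: dict[int, float],
    water_delta: float,
    config: SyntheticConfig,
    seed: int,
    run_id: str = "sample",
    sample_id: str = "S1",
    treatment: Optional[str] = None,
    replicate: int = 1,
) -> list[PeakMeasurement]:
    """Simulated biphytane peaks for one sample (one or more injections).

    ``true_epsilon`` maps ring number to the moiety's true ²ε_L/W (‰);
    ``abundances`` maps ring number to relative abundance (must sum to 1
    within 1e-6). Peak amplitudes are proportional to abundance.
    """
    config.validate()
    total = sum(abundances.values())
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"abundances must sum to 1 within 1e-6, got {total:.8f}")
    rng = np.random.default_rng(seed)
    peaks = []
    for inj in range(1, config.injections_per_sample + 1):
        for ring, eps in sorted(true_epsilon.items()):
            ab = abundances.get(ring, 0.0)
            if ab <= 0:
                continue
            true_delta = delta_bp_from_epsilon(eps, water_delta)
            diluted = dilute_with_added_h(
                true_delta, config.delta_added_H, config.n_added_h, config.n_total_h
            )
            amplitude = config.sample_total_amplitude * ab
            raw = _instrument(config, diluted, amplitude, rng)
            peaks.append(
                PeakMeasurement(
                    run_id=run_id,
                    injection=inj,
                    compound=f"BP-{ring}",
                    amplitude=amplitude,
                    rt_s=1800.0 + 90.0 * ring,
                    area_Vs=amplitude * 2e-3,
                    d2H_raw=raw,
                    is_standard=False,
                    sample_id=sample_id,
                    treatment=treatment,
                    replicate=replicate,
                )
            )
    return peaks


def generate_growth_curve(
    mu: float,
    od0: float,
    times: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
    max_od: Optional[float] = None,
    culture_id: str = "C1",
) -> GrowthCurve:
    """OD(t) = od0·exp(μ·t)·(1 + noise), optionally plateauing at max_od."""
    if mu < 0:
        raise ValueError(f"mu must be >= 0, got {mu}")
    if od0 <= 0:
        raise ValueError(f"od0 must be > 0, got {od0}")
    t = np.asarray(times, dtype=float)
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    od = od0 * np.exp(mu * t)
    if max_od is not None:
        od = np.minimum(od, max_od)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        od = od * (1.0 + rng.normal(0.0, noise_sd, size=od.shape))
        od = np.clip(od, 1e-6, None)
    return GrowthCurve(culture_id=culture_id, times=t, od600=od)


def generate_study(config: SyntheticConfig, seed: Optional[int] = None) -> StudyDataset:
    """A full seeded study: treatments × replicates, each with standards,
    sample peaks, a water δ²H, and a growth curve.

    Per culture the generator draws a water δ²H uniformly over
    ``water_delta_range``, a BP-0 true ε from
    N(true_epsilon_mean, true_epsilon_sd), adds
    ``ring_enrichment_per_ring``·ring for higher moieties, and an
    abundance 4-vector from the configured Dirichlet. Deterministic for a
    fixed seed; the truth table covers every culture.
    """
    config.validate()
    master = np.random.default_rng(config.seed if seed is None else seed)
    standards: list[PeakMeasurement] = []
    samples: list[PeakMeasurement] = []
    waters: dict[str, float] = {}
    curves: dict[str, GrowthCurve] = {}
    meta_rows = []
    truth_rows = []
    w_lo, w_hi = config.water_delta_range
    for ti in range(1, config.n_treatments + 1):
        treatment = f"T{ti}"
        for rep in range(1, config.replicates_per_treatment + 1):
            culture = f"{treatment}-r{rep}"
            run_id = f"run-{culture}"
            sub = np.random.default_rng(master.integers(0, 2**31 - 1))
            water = float(sub.uniform(w_lo, w_hi))
            eps0 = float(sub.normal(config.true_epsilon_mean, config.true_epsilon_sd))
            eps = {r: eps0 + config.ring_enrichment_per_ring * r for r in range(4)}
            ab_vec = sub.dirichlet(config.abundance_dirichlet_params)
            ab_vec = ab_vec / ab_vec.sum()
            abundances = {r: float(ab_vec[r]) for r in range(4)}
            mu = float(sub.uniform(*config.mu_range))
            horizon = min(6.0 * np.log(2) / mu, 120.0)
            times = np.linspace(0.0, horizon, 20)
            curve = generate_growth_curve(
                mu,
                od0=0.006,
                times=times,
                noise_sd=config.growth_noise_sd,
                seed=int(sub.integers(0, 2**31 - 1)),
                max_od=1.5,
                culture_id=culture,
            )
            standards.extend(
                generate_standards_run(
                    config, seed=int(sub.integers(0, 2**31 - 1)), run_id=run_id
                )
            )
            samples.extend(
                generate_sample_run(
                    eps,
                    abundances,
                    water,
                    config,
                    seed=int(sub.integers(0, 2**31 - 1)),
                    run_id=run_id,
                    sample_id=culture,
                    treatment=treatment,
                    replicate=rep,
                )
            )
            waters[culture] = water
            curves[culture] = curve
            meta_rows.append(
                {
                    "culture_id": culture,
                    "experiment": "synthetic",
                    "treatment": treatment,
                    "level": float(ti),
                    "replicate": rep,
                    "d2H_water_permil": water,
                    "culture_type": "chemostat" if config.chemostat else "batch",
                    "dilution_td_h": (np.log(2) / mu) if config.chemostat else np.nan,
                }
            )
            truth_rows.append(
                {
                    "culture_id": culture,
                    "treatment": treatment,
                    "replicate": rep,
                    "water_delta": water,
                    "mu": mu,
                    **{f"eps_bp{r}": eps[r] for r in range(4)},
                    **{f"abundance_bp{r}": abundances[r] for r in range(4)},
                }
            )
    return StudyDataset(
        standards_runs=standards,
        sample_runs=samples,
        water_deltas=waters,
        growth_curves=curves,
        metadata=pd.DataFrame(meta_rows),
        truth=pd.DataFrame(truth_rows),
    )


def write_study(dataset: StudyDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write a study to TSV tables (truth goes to a separate file)."""
    from .io import write_growth_table, write_peak_table, write_standard_definitions

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "standards": out / "standards.tsv",
        "samples": out / "samples.tsv",
        "metadata": out / "metadata.tsv",
        "growth": out / "growth.tsv",
        "standard_defs": out / "standard_definitions.tsv",
        "truth": out / "truth.tsv",
    }
    write_peak_table(dataset.standards_runs, paths["standards"])
    write_peak_table(dataset.sample_runs, paths["samples"])
    dataset.metadata.to_csv(paths["metadata"], sep="\t", index=False)
    write_growth_table(dataset.growth_curves.values(), paths["growth"])
    write_standard_definitions(dataset.standard_definitions, paths["standard_defs"])
    dataset.truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths
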