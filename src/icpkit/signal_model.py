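"""Synthetic multichannel neuromonitoring cohorts.

Generates 3-day trend recordings (ICP, MAP, AMP at 3-s intervals) with the
statistical structure the downstream index analysis assumes:

* MAP carries a slow vasogenic wave (Lundberg-B range, 30–120 s period) plus
  measurement noise;
* ICP couples to the MAP slow wave through ``reactivity_gain`` (sign and
  magnitude steer PRx), and additionally carries an independent B-wave and
  its own noise;
* AMP follows the exponential pressure–volume relation
  ``a0·exp(elastance_coeff·(ICP − icp_baseline))`` below ``icp_critical``
  (steep-zone compensation, RAP > 0) and declines linearly above it
  (exhausted compensation, RAP < 0), per the Monro–Kellie picture in which a
  small volume increase produces a large ICP rise once reserve is spent;
* a fixed fraction of samples is flagged invalid (monitor dropouts).

Two-group cohorts reproduce the published case-mix of a hypertensive
intracerebral haemorrhage series: a good-prognosis group (GOS IV–V, n = 27)
and a poor-prognosis group (GOS I–III, n = 26), with group-level means/SDs
of mean ICP, CPP, PRx and RAP as the calibration targets. Per-patient
reactivity gain and elastance are obtained from the PRx/RAP targets by
closed-form inversion of the linearised correlation model (see
``gain_for_target_prx`` / ``elastance_for_target_rap``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .indices import TrendSeries

__all__ = [
    "ConfigurationError",
    "SimConfig",
    "CovariateSpec",
    "GroupSpec",
    "CohortSpec",
    "PatientRecord",
    "simulate_patient",
    "simulate_cohort",
    "gain_for_target_prx",
    "elastance_for_target_rap",
    "table1_good_group",
    "table1_poor_group",
]

TWO_PI = 2.0 * math.pi


class ConfigurationError(ValueError):
    """Invalid simulation configuration; the message names the field."""


@dataclass
class SimConfig:
    """Parameters of one synthetic patient recording.

    Units are mmHg for pressures and amplitudes, seconds for periods and the
    sampling interval, hours for the total duration. ``reactivity_gain`` is
    the dimensionless coupling of the MAP slow wave into ICP;
    ``elastance_coeff`` (per mmHg) is the exponent of the AMP–ICP relation;
    above ``icp_critical`` AMP declines instead of rising.
    """

    duration_hours: float = 72.0
    sample_interval_s: float = 3.0
    icp_baseline: float = 10.0
    map_baseline: float = 85.0
    slow_wave_amplitude: float = 4.0
    slow_wave_period_s: float = 60.0
    icp_wave_amplitude: float = 2.0
    icp_wave_period_s: float = 100.0
    reactivity_gain: float = 0.2
    elastance_coeff: float = 0.03
    icp_critical: float = 25.0
    amp_baseline: float = 1.5
    noise_sd_icp: float = 1.5
    noise_sd_map: float = 2.5
    noise_sd_amp: float = 0.3
    dropout_fraction: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if not self.duration_hours > 0:
            raise ConfigurationError("duration_hours must be positive")
        if not self.sample_interval_s > 0:
            raise ConfigurationError("sample_interval_s must be positive")
        if not (0.0 <= self.dropout_fraction < 1.0):
            raise ConfigurationError("dropout_fraction must lie in [0, 1)")
        for name in ("noise_sd_icp", "noise_sd_map", "noise_sd_amp"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        for name in ("slow_wave_period_s", "icp_wave_period_s"):
            if not getattr(self, name) > 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.amp_baseline < 0:
            raise ConfigurationError("amp_baseline must be non-negative")
        if self.slow_wave_amplitude < 0:
            raise ConfigurationError("slow_wave_amplitude must be non-negative")
        if self.icp_wave_amplitude < 0:
            raise ConfigurationError("icp_wave_amplitude must be non-negative")


def simulate_patient(config: SimConfig) -> TrendSeries:
    """Simulate one patient's trend recording.

    Identical config (including seed) yields an identical series. Exactly
    ``round(dropout_fraction · n)`` samples are flagged invalid.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    dt = config.sample_interval_s
    n = int(math.floor(config.duration_hours * 3600.0 / dt))
    t = np.arange(n) * dt

    phase_map, phase_icp = rng.uniform(0.0, TWO_PI, size=2)
    map_wave = config.slow_wave_amplitude * np.sin(
        TWO_PI * t / config.slow_wave_period_s + phase_map
    )
    icp_wave = config.icp_wave_amplitude * np.sin(
        TWO_PI * t / config.icp_wave_period_s + phase_icp
    )
    # Noise is always drawn (then scaled) so the random stream, and hence the
    # waves and dropout pattern, are invariant to which SDs are zero.
    map_channel = (
        config.map_baseline + map_wave + config.noise_sd_map * rng.standard_normal(n)
    )
    icp_channel = (
        config.icp_baseline
        + config.reactivity_gain * map_wave
        + icp_wave
        + config.noise_sd_icp * rng.standard_normal(n)
    )

    e = config.elastance_coeff
    amp_at_critical = config.amp_baseline * math.exp(
        e * (config.icp_critical - config.icp_baseline)
    )
    below = icp_channel <= config.icp_critical
    amp_clean = np.where(
        below,
        config.amp_baseline * np.exp(e * (icp_channel - config.icp_baseline)),
        amp_at_critical - e * amp_at_critical * (icp_channel - config.icp_critical),
    )
    amp_channel = np.clip(
        amp_clean + config.noise_sd_amp * rng.standard_normal(n), 0.0, None
    )

    valid = np.ones(n, dtype=bool)
    n_drop = int(round(config.dropout_fraction * n))
    if n_drop:
        valid[rng.choice(n, size=n_drop, replace=False)] = False

    return TrendSeries(
        sample_interval_s=dt,
        icp=icp_channel,
        map=map_channel,
        amp=amp_channel,
        valid=valid,
    )


# --- calibration helpers -----------------------------------------------------

def gain_for_target_prx(target_prx: float, sim: SimConfig) -> float:
    """Reactivity gain that yields a given expected PRx under ``sim``.

    Within a correlation window the MAP signal has variance
    A²/2 + σ_map² (slow wave of amplitude A plus noise) and ICP has variance
    g²·A²/2 + B²/2 + σ_icp² (coupled wave, independent B-wave of amplitude B,
    noise); their covariance is g·A²/2. Solving corr = target for g gives the
    closed form used here. Targets too large for the configured wave-to-noise
    ratio are rejected.
    """
    s_sw = sim.slow_wave_amplitude**2 / 2.0
    if s_sw <= 0:
        raise ConfigurationError("slow_wave_amplitude must be positive to steer PRx")
    s_map = s_sw + sim.noise_sd_map**2
    c = sim.icp_wave_amplitude**2 / 2.0 + sim.noise_sd_icp**2
    denom = s_sw - target_prx**2 * s_map
    if denom <= 0:
        raise ConfigurationError(
            f"target PRx {target_prx:.3f} unreachable with this wave-to-noise ratio"
        )
    return float(target_prx * math.sqrt(s_map * c / (s_sw * denom)))


def elastance_for_target_rap(
    target_rap: float, sim: SimConfig, gain: Optional[float] = None
) -> float:
    """Elastance coefficient that yields a given expected (steep-zone) RAP.

    Linearising AMP ≈ a0·(1 + E·ΔICP) around the baseline, the AMP–ICP
    correlation is k/√(k² + σ_amp²) with k = E·a0·σ_icp, which inverts to
    k = ρ·σ_amp/√(1−ρ²). Requires 0 < ρ < 1 and positive AMP noise.
    """
    if not (0.0 < target_rap < 1.0):
        raise ConfigurationError("target RAP must lie in (0, 1) for the steep zone")
    if sim.noise_sd_amp <= 0 or sim.amp_baseline <= 0:
        raise ConfigurationError("amp noise and baseline must be positive to steer RAP")
    g = sim.reactivity_gain if gain is None else gain
    s_icp = math.sqrt(
        g**2 * sim.slow_wave_amplitude**2 / 2.0
        + sim.icp_wave_amplitude**2 / 2.0
        + sim.noise_sd_icp**2
    )
    k = target_rap * sim.noise_sd_amp / math.sqrt(1.0 - target_rap**2)
    return float(k / (sim.amp_baseline * s_icp))


# --- cohort specification ----------------------------------------------------

@dataclass
class CovariateSpec:
    """Per-group covariate distributions (admission characteristics)."""

    age_mean: float = 64.0
    age_sd: float = 12.0
    male_fraction: float = 0.5
    gcs_values: tuple[int, ...] = (4, 5, 6, 7, 8, 9)
    gcs_weights: tuple[float, ...] = (0.15, 0.2, 0.25, 0.2, 0.12, 0.08)
    hematoma_mean: float = 36.0
    hematoma_sd: float = 6.5
    hematoma_range: tuple[float, float] = (20.0, 50.0)
    gos_values: tuple[int, ...] = (4, 5)
    gos_weights: tuple[float, ...] = (0.5, 0.5)


@dataclass
class GroupSpec:
    """One prognosis group: signal template plus between-patient spread.

    ``prx_mean/sd`` and ``rap_mean/sd`` are targets on the index scale; each
    patient's reactivity gain and elastance are derived from a draw of these
    targets via the calibration inversions.
    """

    name: str
    sim: SimConfig
    icp_baseline_mean: float
    icp_baseline_sd: float
    cpp_mean: float
    cpp_sd: float
    prx_mean: float
    prx_sd: float
    rap_mean: float
    rap_sd: float
    cov: CovariateSpec


def table1_good_group() -> GroupSpec:
    """Good-prognosis (GOS IV–V) group calibrated to the published case-mix."""
    return GroupSpec(
        name="good",
        sim=SimConfig(icp_critical=60.0),
        icp_baseline_mean=10.12,
        icp_baseline_sd=4.37,
        cpp_mean=73.65,
        cpp_sd=8.27,
        prx_mean=0.05,
        prx_sd=0.098,
        rap_mean=0.14,
        rap_sd=0.10,
        cov=CovariateSpec(
            age_mean=63.67,
            age_sd=11.84,
            male_fraction=14.0 / 27.0,
            gcs_weights=(0.08, 0.12, 0.2, 0.25, 0.2, 0.15),
            hematoma_mean=35.41,
            hematoma_sd=6.63,
            gos_values=(4, 5),
            gos_weights=(0.5, 0.5),
        ),
    )


def table1_poor_group() -> GroupSpec:
    """Poor-prognosis (GOS I–III) group calibrated to the published case-mix."""
    return GroupSpec(
        name="poor",
        sim=SimConfig(icp_critical=60.0),
        icp_baseline_mean=27.68,
        icp_baseline_sd=13.17,
        cpp_mean=55.88,
        cpp_sd=14.68,
        prx_mean=0.34,
        prx_sd=0.12,
        rap_mean=0.37,
        rap_sd=0.12,
        cov=CovariateSpec(
            age_mean=64.58,
            age_sd=13.62,
            male_fraction=13.0 / 26.0,
            gcs_weights=(0.15, 0.2, 0.25, 0.2, 0.12, 0.08),
            hematoma_mean=37.38,
            hematoma_sd=6.40,
            gos_values=(1, 2, 3),
            gos_weights=(0.05, 0.05, 0.9),
        ),
    )


@dataclass
class CohortSpec:
    """Two-group cohort specification; defaults reproduce the study design."""

    n_good: int = 27
    n_poor: int = 26
    good: GroupSpec = field(default_factory=table1_good_group)
    poor: GroupSpec = field(default_factory=table1_poor_group)
    seed: int = 0

    def validate(self) -> None:
        if self.n_good < 2 or self.n_poor < 2:
            raise ConfigurationError(
                "n_good and n_poor must each be at least 2 (two-group tests undefined otherwise)"
            )


@dataclass
class PatientRecord:
    """Covariates, outcome group and (optionally) the attached recording."""

    patient_id: str
    group: str
    age: int
    sex: str
    gcs: int
    hematoma_ml: float
    gos: int
    series: Optional[TrendSeries] = None
    sim_config: Optional[SimConfig] = None


def _fold_seed(master: int, j: int) -> int:
    """Deterministic per-patient seed: arithmetic fold of (master, index)."""
    return (int(master) * 1_000_003 + j * 10_007 + 12_345) % (2**31)


def _draw_patient(
    spec: GroupSpec, cov_rng: np.random.Generator, sig_seed: int
) -> tuple[SimConfig, dict]:
    icp_b = max(3.0, cov_rng.normal(spec.icp_baseline_mean, spec.icp_baseline_sd))
    cpp_b = float(np.clip(cov_rng.normal(spec.cpp_mean, spec.cpp_sd), 20.0, 130.0))
    prx_t = float(np.clip(cov_rng.normal(spec.prx_mean, spec.prx_sd), -0.85, 0.85))
    rap_t = float(np.clip(cov_rng.normal(spec.rap_mean, spec.rap_sd), 0.01, 0.90))
    gain = gain_for_target_prx(prx_t, spec.sim)
    elast = elastance_for_target_rap(rap_t, spec.sim, gain)
    cfg = replace(
        spec.sim,
        icp_baseline=icp_b,
        map_baseline=icp_b + cpp_b,
        reactivity_gain=gain,
        elastance_coeff=elast,
        seed=sig_seed,
    )
    c = spec.cov
    covars = {
        "age": int(round(float(np.clip(cov_rng.normal(c.age_mean, c.age_sd), 18, 95)))),
        "sex": "M" if cov_rng.uniform() < c.male_fraction else "F",
        "gcs": int(cov_rng.choice(c.gcs_values, p=np.asarray(c.gcs_weights) / np.sum(c.gcs_weights))),
        "hematoma_ml": float(
            np.clip(cov_rng.normal(c.hematoma_mean, c.hematoma_sd), *c.hematoma_range)
        ),
        "gos": int(cov_rng.choice(c.gos_values, p=np.asarray(c.gos_weights) / np.sum(c.gos_weights))),
    }
    return cfg, covars


def simulate_cohort(spec: CohortSpec, attach_series: bool = True) -> list[PatientRecord]:
    """Simulate a full two-group cohort.

    Good-prognosis patients come first, then poor-prognosis. Per-patient
    seeds are folded deterministically from the master seed, so the same
    spec yields a bitwise-identical cohort.
    """
    spec.validate()
    records: list[PatientRecord] = []
    idx = 0
    for group_spec, n in ((spec.good, spec.n_good), (spec.poor, spec.n_poor)):
        for _ in range(n):
            cov_rng = np.random.default_rng(_fold_seed(spec.seed, 2 * idx))
            sig_seed = _fold_seed(spec.seed, 2 * idx + 1)
            cfg, covars = _draw_patient(group_spec, cov_rng, sig_seed)
            series = simulate_patient(cfg) if attach_series else None
            records.append(
                PatientRecord(
                    patient_id=f"pt{idx:03d}",
                    group=group_spec.name,
                    series=series,
                    sim_config=cfg,
                    **covars,
                )
            )
            idx += 1
    return records
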