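"""Synthetic participant cohort, trial schedules, and ground-truth vessel dynamics.

The lognormal spread of the venous gain is narrower than the published
fitted-slope interquartile ranges because printed slopes from 3-4 noisy
points carry estimation noise on top of the true between-person spread; the
sigmas here are chosen so that *fitted* per-participant slopes under the
default noise model reproduce the published IQR ratios.

Participants are sampled around published sex-stratified anthropometric and
vascular characteristics of healthy young adults: internal jugular vein (IJV)
cross-sectional area (CSA) and optical attenuation (JVA) at supine baseline,
sternocleidomastoid thickness, depth from skin to the IJV, and a ~15% higher
hemoglobin concentration in men.  Each participant also carries a personal
attenuation-versus-CSA gain (a.u. per cm**2) whose sex-specific medians and
spreads follow the published per-participant regression slopes, plus personal
fluid-shift response magnitudes for head-down tilt (HDT) and lower-body
negative pressure (LBNP).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from . import waveforms

__all__ = [
    "SEX_PARAMS",
    "HDT_LEVELS",
    "LBNP_LEVELS",
    "ParticipantModel",
    "ConditionLevel",
    "VesselDynamics",
    "make_cohort",
    "schedule_trials",
    "true_csa",
    "render_dynamics",
    "truncnorm_mean",
]

# Sex-stratified sampling parameters: (mean, SD) pairs reflect published
# participant characteristics of healthy young adults; jva_gain is lognormal
# with median anchored to the published per-participant LBNP slopes and sigma
# matched to the published interquartile ranges.
SEX_PARAMS = {
    "F": {
        "age": (24.0, 4.0),
        "bsa": (1.61, 0.16),
        "bmi": (22.2, 2.1),
        "csa_baseline": (0.60, 0.18),
        "jva_baseline": (0.51, 0.07),
        "scm_thickness": (0.81, 0.14),
        "ijv_depth": (1.17, 0.12),
        "hb_scale": (1.00, 0.07),
        "jva_gain_median": 0.05,
        "jva_gain_sigma": 0.69,
    },
    "M": {
        "age": (25.0, 5.0),
        "bsa": (1.90, 0.15),
        "bmi": (23.7, 3.1),
        "csa_baseline": (0.44, 0.25),
        "jva_baseline": (0.61, 0.09),
        "scm_thickness": (1.13, 0.23),
        "ijv_depth": (1.51, 0.21),
        "hb_scale": (1.15, 0.0805),
        "jva_gain_median": 0.23,
        "jva_gain_sigma": 0.70,
    },
}

HDT_LEVELS: tuple[float, ...] = (0.0, -3.0, -6.0)      # degrees
LBNP_LEVELS: tuple[float, ...] = (0.0, -20.0, -30.0, -40.0)  # mmHg

# Fluid-shift response magnitudes (group means; between-person SD):
# HDT raises CSA by ~0.2 cm**2 at -6 deg, consistent with reported group
# increases of 0.15-0.23 cm**2 within minutes of mild HDT; the between-person
# spread is wide enough that a few participants per cohort barely respond
# (the study saw 3/19 with < 0.15 cm**2 HDT change and inverse JVA-CSA
# association).  LBNP lowers CSA toward a collapse floor, removing up to
# ~70% of the baseline-minus-floor area at -40 mmHg.
HDT_DELTA = (0.17, 0.11)           # cm**2 at -6 degrees
HDT_DELTA_MIN = 0.01               # cm**2, smallest responder
LBNP_MAX_REDUCTION = (0.70, 0.10)  # fraction of (baseline - floor) at -40 mmHg
CSA_FLOOR = 0.05                   # cm**2, vein-collapse floor


@dataclass(frozen=True)
class ParticipantModel:
    """Anatomy/physiology parameters driving both rendering and ground truth."""

    id: str
    sex: str                 # {"M", "F"}
    hb_scale: float          # relative hemoglobin concentration (F mean = 1.0)
    scm_thickness: float     # sternocleidomastoid thickness, cm
    ijv_depth: float         # skin surface to vessel centroid, cm
    csa_baseline: float      # supine 0-degree HDT CSA, cm**2
    jva_gain: float          # attenuation-vs-CSA slope, a.u. per cm**2
    heart_rate: float        # beats/min
    resp_rate: float         # breaths/min
    hdt_delta: float         # CSA increase at -6 deg HDT, cm**2
    lbnp_max_reduction: float  # fractional CSA reduction at -40 mmHg
    age: float = np.nan
    bsa: float = np.nan
    bmi: float = np.nan

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise ValueError(f"sex must be 'M' or 'F', got {self.sex!r}")
        for name in ("hb_scale", "scm_thickness", "ijv_depth", "csa_baseline", "jva_gain"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 <= self.lbnp_max_reduction < 1.0):
            raise ValueError("lbnp_max_reduction must lie in [0, 1)")


@dataclass(frozen=True)
class ConditionLevel:
    """One orthostatic challenge level: HDT angle (deg) or LBNP suction (mmHg)."""

    condition: str
    level: float

    def __post_init__(self) -> None:
        if self.condition == "HDT":
            allowed = HDT_LEVELS
        elif self.condition == "LBNP":
            allowed = LBNP_LEVELS
        else:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.level not in allowed:
            raise ValueError(f"{self.condition} level must be one of {allowed}")


@dataclass(frozen=True)
class VesselDynamics:
    """Instantaneous jugular CSA over one acquisition.

    CSA(t) = mean_csa * (1 + cardiac_waveform(t) + resp(t)) with the cardiac
    component anti-phase to the arterial PPG generated under the same seed.
    """

    mean_csa: float
    cardiac_waveform: np.ndarray   # unitless, zero-mean, includes amplitude
    resp_mod_amplitude: float      # fraction of mean_csa
    resp_rate: float               # breaths/min
    resp_phase: float              # radians
    duration: float
    sample_rate: float

    def __post_init__(self) -> None:
        if self.mean_csa <= 0:
            raise ValueError("mean_csa must be positive")
        if np.abs(self.cardiac_waveform).max(initial=0.0) >= 0.5:
            raise ValueError("cardiac modulation must stay below 50% of mean CSA")
        if not (0.0 <= self.resp_mod_amplitude < 0.5):
            raise ValueError("respiratory modulation must stay below 50% of mean CSA")

    @property
    def times(self) -> np.ndarray:
        n = int(round(self.duration * self.sample_rate))
        return np.arange(n) / self.sample_rate

    def resp_component(self) -> np.ndarray:
        w = 2.0 * np.pi * self.resp_rate / 60.0
        return self.resp_mod_amplitude * np.sin(w * self.times + self.resp_phase)

    def csa_series(self) -> np.ndarray:
        """Instantaneous CSA (cm**2) at every sample; always positive."""
        return self.mean_csa * (1.0 + self.cardiac_waveform + self.resp_component())


def _trunc_sampler(mean: float, sd: float, lo: float | None = None, hi: float | None = None):
    """Truncated-normal frozen distribution; default bounds 3 SD and zero."""
    if lo is None:
        lo = max(0.0, mean - 3.0 * sd)
    if hi is None:
        hi = mean + 3.0 * sd
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return sps.truncnorm(a, b, loc=mean, scale=sd)


def truncnorm_mean(mean: float, sd: float, lo: float | None = None, hi: float | None = None) -> float:
    """Analytic mean of the truncated-normal sampler used for a given field."""
    return float(_trunc_sampler(mean, sd, lo, hi).mean())


def _sample_sex(sex: str, n: int, rng: np.random.Generator, id_offset: int = 0) -> list[ParticipantModel]:
    p = SEX_PARAMS[sex]
    draws = {
        key: _trunc_sampler(*p[key]).rvs(size=n, random_state=rng)
        for key in ("age", "bsa", "bmi", "csa_baseline", "scm_thickness", "ijv_depth", "hb_scale")
    }
    gains = p["jva_gain_median"] * np.exp(p["jva_gain_sigma"] * rng.standard_normal(n))
    hdt = _trunc_sampler(*HDT_DELTA, lo=HDT_DELTA_MIN).rvs(size=n, random_state=rng)
    lbnp = _trunc_sampler(*LBNP_MAX_REDUCTION, lo=0.30, hi=0.95).rvs(size=n, random_state=rng)
    hr = rng.uniform(60.0, 80.0, size=n)
    rr = rng.uniform(12.0, 16.0, size=n)
    return [
        ParticipantModel(
            id=f"{sex}{i + 1 + id_offset:02d}",
            sex=sex,
            hb_scale=float(draws["hb_scale"][i]),
            scm_thickness=float(draws["scm_thickness"][i]),
            ijv_depth=float(draws["ijv_depth"][i]),
            csa_baseline=float(draws["csa_baseline"][i]),
            jva_gain=float(gains[i]),
            heart_rate=float(hr[i]),
            resp_rate=float(rr[i]),
            hdt_delta=float(hdt[i]),
            lbnp_max_reduction=float(lbnp[i]),
            age=float(draws["age"][i]),
            bsa=float(draws["bsa"][i]),
            bmi=float(draws["bmi"][i]),
        )
        for i in range(n)
    ]


def make_cohort(n_men: int, n_women: int, seed: int) -> list[ParticipantModel]:
    """Sample a cohort of ``n_men`` + ``n_women`` participants.

    Women are sampled first so that the stream for either sex is stable when
    only the other count changes.  Reproducible given ``seed``.
    """
    if n_men < 1 or n_women < 1:
        raise ValueError("cohort requires at least one participant of each sex")
    ss = np.random.SeedSequence(int(seed))
    rng_f, rng_m = (np.random.default_rng(c) for c in ss.spawn(2))
    return _sample_sex("F", n_women, rng_f) + _sample_sex("M", n_men, rng_m)


def schedule_trials(participant: ParticipantModel, seed: int) -> list[ConditionLevel]:
    """Condition schedule: block order randomized, levels within a block fixed."""
    rng = np.random.default_rng(int(seed))
    hdt = [ConditionLevel("HDT", lv) for lv in HDT_LEVELS]
    lbnp = [ConditionLevel("LBNP", lv) for lv in LBNP_LEVELS]
    return hdt + lbnp if rng.random() < 0.5 else lbnp + hdt


def csa_floor(participant: ParticipantModel) -> float:
    """Collapse floor for this participant (cm**2), below their baseline."""
    return min(CSA_FLOOR, 0.5 * participant.csa_baseline)


def true_csa(participant: ParticipantModel, cond: ConditionLevel) -> float:
    """Ground-truth mean CSA (cm**2) at one condition level.

    HDT distends the vein linearly with tilt angle; LBNP shrinks it linearly
    with suction toward a collapse floor.  Equals ``csa_baseline`` at level 0
    of either condition; deterministic.
    """
    b = participant.csa_baseline
    if cond.condition == "HDT":
        return b + (abs(cond.level) / 6.0) * participant.hdt_delta
    if cond.condition == "LBNP":
        floor = csa_floor(participant)
        frac = (abs(cond.level) / 40.0) * participant.lbnp_max_reduction
        return floor + (b - floor) * (1.0 - frac)
    raise ValueError(f"unknown condition {cond.condition!r}")


def render_dynamics(
    participant: ParticipantModel,
    cond: ConditionLevel,
    duration: float,
    fs: float,
    seed: int,
    cardiac_amp: float = 0.08,
    resp_amp: float = 0.05,
    jitter: float = 0.02,
) -> VesselDynamics:
    """Ground-truth CSA time series for one acquisition.

    The cardiac component uses the shared beat clock, so it is anti-phase
    with the arterial PPG produced by ``optics.generate_ppg`` under the same
    seed and heart rate.
    """
    if duration <= 0 or fs <= 0:
        raise ValueError("duration and fs must be positive")
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    spikes = waveforms.beat_times(participant.heart_rate, duration, seed, jitter=jitter)
    cardiac = cardiac_amp * waveforms.venous_series(t, spikes)
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 2)))
    phase = float(rng.uniform(0.0, 2.0 * np.pi)) if resp_amp > 0 else 0.0
    return VesselDynamics(
        mean_csa=true_csa(participant, cond),
        cardiac_waveform=cardiac,
        resp_mod_amplitude=resp_amp,
        resp_rate=participant.resp_rate,
        resp_phase=phase,
        duration=duration,
        sample_rate=fs,
    )
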