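"""End-to-end experiment orchestration.

Two complementary forward paths share one parameterization:

* ``run_experiment`` renders near-infrared video for every trial and pushes
  it through the full extraction chain (down-sample, calibrate, denoise,
  anticorrelation localization) alongside the simulated ultrasound stage —
  the imaging-faithful path, used at desk scale.
* ``simulate_trial_table`` evaluates the same optical model analytically
  (region-mean attenuation = static tissue term + realized gain x CSA) with
  measurement noise — the fast path used for statistical Monte Carlo, where
  hundreds of cohorts are needed.

The venous ROI is localized at the level-0 acquisition of each
(participant, condition) block and reused across that block's levels,
emulating extraction from the same ~1 cm vessel segment throughout a
condition.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import chi, csa as csa_mod, io, optics, stats
from .cohort import (
    ConditionLevel,
    ParticipantModel,
    make_cohort,
    render_dynamics,
    schedule_trials,
    true_csa,
)
from .optics import DEPTH_DELTA, DEPTH_REF, BACKGROUND_MU, MU_MYO, NoiseConfig

logger = logging.getLogger("chijva")

__all__ = [
    "ExperimentConfig",
    "subseed",
    "realized_gain",
    "static_attenuation",
    "run_trial",
    "run_experiment",
    "simulate_trial_table",
    "simulate_common_slope_table",
    "make_fixtures",
]


def subseed(*key) -> int:
    """Deterministic sub-stream seed (< 2**31) for a hierarchical key."""
    return int(np.random.SeedSequence(tuple(int(k) for k in key)).generate_state(1)[0] & 0x7FFFFFFF)


@dataclass(frozen=True)
class ExperimentConfig:
    """All knobs of one synthetic study run."""

    n_men: int = 10
    n_women: int = 10
    seed: int = 0
    duration: float = 30.0       # s per acquisition
    fs: float = 60.0             # video frame rate, Hz
    scene_shape: tuple[int, int] = (64, 64)
    pixel_pitch: float = 0.05    # cm per pixel
    cardiac_amp: float = 0.08    # venous pulse, fraction of mean CSA
    resp_amp: float = 0.05       # respiratory modulation, fraction of mean CSA
    jitter: float = 0.02         # cardiac cycle-length jitter
    shot_scale: float = 2e-6     # sensor shot-noise variance scale
    read_sd: float = 2e-3        # sensor read-noise SD
    ppg_noise_sd: float = 0.01
    csa_noise_sd: float = 0.02   # cm**2 operator noise in the ultrasound stage
    csa_resid_sd: float = 0.06   # cm**2 venous-volume fluctuation between snapshots
    jva_noise_sd: float = 0.002  # a.u. additive sensor floor in the analytic path
    r_threshold: float = -0.3
    kalman_process_var: float = 1e-3
    kalman_meas_var: float = 1e-3
    roi_cap_cm: float = 1.0      # vessel-axis extent cap of the extraction segment
    emulate_dropouts: bool = True

    @classmethod
    def fast(cls, **kw) -> "ExperimentConfig":
        """Reduced acquisition (10 s at 30 fps) for desk-scale runs."""
        kw.setdefault("duration", 10.0)
        kw.setdefault("fs", 30.0)
        return cls(**kw)

    @classmethod
    def noise_free(cls, **kw) -> "ExperimentConfig":
        """Sensor, operator, and respiratory variability disabled.

        The cardiac venous pulse is kept (it is the localization signal and
        scales with mean CSA), while cycle jitter, respiration, and every
        noise source are zeroed — so the extracted outcomes are exact,
        deterministic functions of the ground-truth CSA.
        """
        kw.setdefault("duration", 10.0)
        kw.setdefault("fs", 30.0)
        kw.update(
            shot_scale=0.0, read_sd=0.0, ppg_noise_sd=0.0, csa_noise_sd=0.0,
            csa_resid_sd=0.0, jva_noise_sd=0.0, resp_amp=0.0, jitter=0.0,
        )
        return cls(**kw)

    def noise_config(self) -> NoiseConfig:
        return NoiseConfig(shot_scale=self.shot_scale, read_sd=self.read_sd)

    def roi_cap_px(self) -> int:
        return int(np.ceil(self.roi_cap_cm / (4.0 * self.pixel_pitch)))

    def to_toml(self, path) -> None:
        lines = []
        for k, v in asdict(self).items():
            if isinstance(v, tuple):
                v = list(v)
            lines.append(f"{k} = {json.dumps(v)}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_toml(cls, path) -> "ExperimentConfig":
        import tomllib

        raw = tomllib.loads(Path(path).read_text())
        if "scene_shape" in raw:
            raw["scene_shape"] = tuple(raw["scene_shape"])
        return cls(**raw)


def realized_gain(p: ParticipantModel) -> float:
    """Attenuation-vs-CSA slope the optics realize for this participant.

    The sampled venous gain modulated by relative hemoglobin and by depth
    sensitivity against the reference depth.
    """
    d = optics.depth_factor(p.ijv_depth, DEPTH_DELTA) / optics.depth_factor(DEPTH_REF, DEPTH_DELTA)
    return p.jva_gain * p.hb_scale * d


def static_attenuation(p: ParticipantModel) -> float:
    """CSA-independent attenuation: background plus two-pass muscle term."""
    return BACKGROUND_MU + 2.0 * MU_MYO * p.scm_thickness


def run_trial(
    participant: ParticipantModel,
    cond: ConditionLevel,
    config: ExperimentConfig,
    seed: int,
    roi: chi.VenousROI | None = None,
    scene: optics.SceneModel | None = None,
):
    """Render one acquisition and extract (peak JVA, measured CSA).

    Returns a dict with the trial outcomes plus the ROI used (or None when
    no venous region was localized, in which case the trial is dropped by
    the caller).
    """
    if scene is None:
        scene = optics.build_scene(
            participant, shape=config.scene_shape, pixel_pitch=config.pixel_pitch
        )
    dynamics = render_dynamics(
        participant, cond, config.duration, config.fs, seed,
        cardiac_amp=config.cardiac_amp, resp_amp=config.resp_amp, jitter=config.jitter,
    )
    signals = optics.generate_ppg(
        participant.heart_rate, config.duration, config.fs, seed,
        jitter=config.jitter, noise_sd=config.ppg_noise_sd,
    )
    noise = config.noise_config()
    stack = optics.render_stack(
        scene, participant, dynamics, signals,
        noise_cfg=None if (noise.shot_scale == 0 and noise.read_sd == 0) else noise,
        seed=subseed(seed, 11),
    )
    jva_res, roi_out, cmap, _ = chi.process_stack(
        stack, signals,
        target_mask=scene.target_mask(), r_ref=scene.r_ref,
        midline_row=scene.midline_row, r_threshold=config.r_threshold,
        process_var=config.kalman_process_var, meas_var=config.kalman_meas_var,
        max_extent_px=config.roi_cap_px(), roi=roi,
    )
    loop = csa_mod.simulate_cine_loop(
        participant, cond, subseed(seed, 12),
        cardiac_amp=config.cardiac_amp, resp_amp=config.resp_amp, jitter=config.jitter,
    )
    meas = csa_mod.measure_csa(loop, noise_sd=config.csa_noise_sd, seed=subseed(seed, 13))
    return {
        "participant": participant.id,
        "sex": participant.sex,
        "condition": cond.condition,
        "level": cond.level,
        "jva": None if jva_res is None else jva_res.peak,
        "csa": meas.value,
        "true_csa": true_csa(participant, cond),
        "roi": roi_out,
        "cmap": cmap,
    }


def _dropout_sets(cohort: list[ParticipantModel]) -> tuple[set, set]:
    """Emulate the analysed-n structure: one woman fully excluded (imaging
    field of view) and one man's LBNP data excluded (acquisition issues)."""
    women = [p.id for p in cohort if p.sex == "F"]
    men = [p.id for p in cohort if p.sex == "M"]
    drop_all = {women[0]} if len(women) > 1 else set()
    drop_lbnp = {men[0]} if len(men) > 1 else set()
    return drop_all, drop_lbnp


def run_experiment(config: ExperimentConfig, outdir=None) -> dict:
    """Generate cohort, render every trial, extract outcomes, run statistics.

    Deterministic given ``config.seed``.  Returns a dict with the cohort
    table, trial table, and the statistics bundle; writes CSV/JSON/figures
    when ``outdir`` is given.
    """
    cohort = make_cohort(config.n_men, config.n_women, config.seed)
    drop_all, drop_lbnp = (
        _dropout_sets(cohort) if config.emulate_dropouts else (set(), set())
    )

    rows = []
    for pi, p in enumerate(cohort):
        if p.id in drop_all:
            logger.info("dropping participant %s (emulated exclusion)", p.id)
            continue
        scene = optics.build_scene(p, shape=config.scene_shape, pixel_pitch=config.pixel_pitch)
        schedule = schedule_trials(p, subseed(config.seed, pi, 99))
        # Localize the ROI on the level-0 acquisition of each condition block,
        # then hold it fixed across that block.
        block_roi: dict[str, chi.VenousROI | None] = {}
        for ti, cond in enumerate(schedule):
            if cond.condition == "LBNP" and p.id in drop_lbnp:
                continue
            seed = subseed(config.seed, pi, ti)
            if cond.condition not in block_roi:
                base = run_trial(p, ConditionLevel(cond.condition, 0.0), config,
                                 subseed(config.seed, pi, ti, 0), scene=scene)
                block_roi[cond.condition] = base["roi"]
            out = run_trial(p, cond, config, seed, roi=block_roi[cond.condition], scene=scene)
            if out["jva"] is None:
                logger.warning("no venous ROI for %s %s %s; trial dropped",
                               p.id, cond.condition, cond.level)
                continue
            out.pop("roi")
            out.pop("cmap")
            rows.append(out)

    trials = pd.DataFrame(rows)
    base_map = (
        trials[(trials["condition"] == "HDT") & (trials["level"] == 0.0)]
        .set_index("participant")["csa"]
    )
    trials["baseline_csa"] = trials["participant"].map(base_map)

    cohort_df = io.cohort_to_frame(cohort)
    results = {"cohort": cohort_df, "trials": trials, "stats": analyze_trials(trials, cohort_df)}

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        cohort_df.to_csv(outdir / "cohort.csv", index=False)
        trials.to_csv(outdir / "trials.csv", index=False)
        (outdir / "stats.json").write_text(json.dumps(results["stats"], indent=2, default=_json_default))
        _write_figures(trials, outdir)
    return results


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    if hasattr(obj, "__dataclass_fields__"):
        return {k: v for k, v in vars(obj).items()}
    return str(obj)


def analyze_trials(trials: pd.DataFrame, cohort_df: pd.DataFrame | None = None) -> dict:
    """The study's statistical battery over one trial table."""
    out: dict = {"rmcorr": {}, "lmm": {}, "fits": {}, "slope_comparison": {}}
    fits_all: list[stats.IndividualFit] = []
    for cond in ("HDT", "LBNP"):
        sub = trials[trials["condition"] == cond]
        if sub.empty:
            continue
        for sex in ("M", "F"):
            ssub = sub[sub["sex"] == sex]
            try:
                out["rmcorr"][f"{cond}_{sex}"] = vars(stats.rmcorr(ssub))
            except ValueError:
                out["rmcorr"][f"{cond}_{sex}"] = None
        for response in ("jva", "csa"):
            try:
                res = stats.fit_lmm(sub, response=response)
                out["lmm"][f"{cond}_{response}"] = {
                    "p_values": res.p_values,
                    "emm": res.emm,
                    "contrasts": res.contrasts,
                }
            except ValueError as exc:
                out["lmm"][f"{cond}_{response}"] = {"error": str(exc)}
        fits = stats.individual_fits(sub)
        fits_all.extend(fits)
        out["fits"][cond] = stats.summarize_fits(fits)
        m = [f.slope for f in fits if f.sex == "M"]
        f_ = [f.slope for f in fits if f.sex == "F"]
        if m and f_:
            stat, p = stats.compare_slopes(m, f_)
            out["slope_comparison"][cond] = {"statistic": stat, "p": p}
    out["reliability"] = stats.stratify_reliability(fits_all)
    if cohort_df is not None and not trials.empty:
        base = trials[(trials["condition"] == "HDT") & (trials["level"] == 0.0)]
        merged = base.merge(
            cohort_df[["id", "scm_thickness", "ijv_depth"]],
            left_on="participant", right_on="id",
        )
        if len(merged) >= 3:
            out["anthropometric"] = stats.anthropometric_correlations(
                merged.rename(columns={"jva": "jva_baseline"})
            )
    return out


def simulate_trial_table(
    cohort: list[ParticipantModel],
    seed: int,
    config: ExperimentConfig | None = None,
    emulate_dropouts: bool | None = None,
) -> pd.DataFrame:
    """Analytic forward model of the trial table (no video rendering).

    Peak JVA = static tissue attenuation + realized gain x peak instantaneous
    CSA + residual noise; measured CSA comes from the simulated cine-loop
    stage.  The residual JVA noise has two parts: a venous-volume
    fluctuation term (CSA-equivalent SD ``csa_resid_sd``) scaled by the
    participant's realized gain — because the optical and ultrasound
    snapshots are not simultaneous — plus a small additive sensor floor.
    Shares every physiological parameter with the rendered path.
    """
    cfg = config or ExperimentConfig()
    if emulate_dropouts is None:
        emulate_dropouts = cfg.emulate_dropouts
    drop_all, drop_lbnp = _dropout_sets(cohort) if emulate_dropouts else (set(), set())
    peak_mod = 1.0 + cfg.cardiac_amp + cfg.resp_amp
    rows = []
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 77)))
    for pi, p in enumerate(cohort):
        if p.id in drop_all:
            continue
        gain = realized_gain(p)
        static = static_attenuation(p)
        schedule = schedule_trials(p, subseed(seed, pi, 99))
        for ti, cond in enumerate(schedule):
            if cond.condition == "LBNP" and p.id in drop_lbnp:
                continue
            tcsa = true_csa(p, cond)
            jva = (
                static
                + gain * (tcsa * peak_mod + cfg.csa_resid_sd * rng.standard_normal())
                + cfg.jva_noise_sd * rng.standard_normal()
            )
            loop = csa_mod.simulate_cine_loop(
                p, cond, subseed(seed, pi, ti, 12),
                cardiac_amp=cfg.cardiac_amp, resp_amp=cfg.resp_amp, jitter=cfg.jitter,
            )
            meas = csa_mod.measure_csa(loop, noise_sd=cfg.csa_noise_sd, seed=subseed(seed, pi, ti, 13))
            rows.append(
                {
                    "participant": p.id, "sex": p.sex,
                    "condition": cond.condition, "level": cond.level,
                    "jva": jva, "csa": meas.value, "true_csa": tcsa,
                }
            )
    trials = pd.DataFrame(rows)
    base_map = (
        trials[(trials["condition"] == "HDT") & (trials["level"] == 0.0)]
        .set_index("participant")["csa"]
    )
    trials["baseline_csa"] = trials["participant"].map(base_map)
    return trials


def simulate_common_slope_table(
    n_participants: int = 10,
    k: int = 4,
    slope: float = 0.1,
    noise_sd: float = 0.005,
    seed: int = 0,
    x_spread: float = 0.4,
) -> pd.DataFrame:
    """Trial table with a known common JVA-vs-CSA slope for recovery checks.

    Every participant shares ``slope``; intercepts and covariate ranges vary
    between participants.
    """
    rng = np.random.default_rng(int(seed))
    rows = []
    for i in range(n_participants):
        intercept = rng.uniform(0.4, 0.7)
        x0 = rng.uniform(0.3, 0.7)
        x = x0 + np.linspace(0.0, x_spread, k) + rng.normal(0, 0.02, k)
        y = intercept + slope * x + rng.normal(0, noise_sd, k)
        for j in range(k):
            rows.append(
                {"participant": f"P{i:02d}", "sex": "M" if i % 2 else "F",
                 "condition": "LBNP", "level": float(-10 * j),
                 "csa": x[j], "jva": y[j]}
            )
    return pd.DataFrame(rows)


def make_fixtures(seed: int, outdir=None) -> dict:
    """Small ground-truth scene/stack/signal bundle for unit tests.

    16 x 16 pixels at 0.1 cm/px, 4 s at 30 fps (120 frames), noise-free,
    with the vessel segment aligned to the down-sampling grid so the
    down-sampled ground-truth mask is exact.
    """
    p = ParticipantModel(
        id="FIX1", sex="F", hb_scale=1.0, scm_thickness=0.8, ijv_depth=1.2,
        csa_baseline=0.30, jva_gain=0.15, heart_rate=66.0, resp_rate=14.0,
        hdt_delta=0.2, lbnp_max_reduction=0.7,
    )
    scene = optics.SceneModel(
        shape=(16, 16), pixel_pitch=0.1, midline_row=6, vessel_row=11,
        vessel_cols=(4, 16), artery_rows=(7, 8), artery_amp=0.02,
        target=(slice(0, 4), slice(0, 4)), r_ref=0.95,
        mu_blood=p.jva_gain / (optics.depth_factor(DEPTH_REF) * 2.0 / (0.1 * 8)),
        scm_thickness=p.scm_thickness,
    )
    cond = ConditionLevel("HDT", 0.0)
    dynamics = render_dynamics(p, cond, 4.0, 30.0, seed, cardiac_amp=0.08, resp_amp=0.04)
    signals = optics.generate_ppg(p.heart_rate, 4.0, 30.0, seed, noise_sd=0.0)
    stack = optics.render_stack(scene, p, dynamics, signals, noise_cfg=None)
    out = {
        "participant": p, "scene": scene, "cond": cond,
        "dynamics": dynamics, "signals": signals, "stack": stack,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        io.write_stack(outdir / "fixture_stack.tiff", stack)
        io.write_signals(outdir / "fixture_signals.csv", signals)
    return out


def _write_figures(trials: pd.DataFrame, outdir: Path) -> None:
    """Boxplots per condition level by sex, and the JVA-vs-CSA scatter."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for cond in ("HDT", "LBNP"):
        sub = trials[trials["condition"] == cond]
        if sub.empty:
            continue
        fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
        for ax, var in zip(axes, ("csa", "jva")):
            levels = sorted(sub["level"].unique(), key=abs)
            data, labels = [], []
            for lv in levels:
                for sex in ("F", "M"):
                    data.append(sub[(sub["level"] == lv) & (sub["sex"] == sex)][var].dropna())
                    labels.append(f"{lv:g}\n{sex}")
            ax.boxplot(data, tick_labels=labels)
            ax.set_title(f"{var.upper()} vs {cond} level")
        fig.tight_layout()
        fig.savefig(outdir / f"fig_{cond.lower()}.png", dpi=110)
        plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 4))
    for sex, marker in (("F", "o"), ("M", "^")):
        sub = trials[trials["sex"] == sex]
        ax.scatter(sub["csa"], sub["jva"], marker=marker, s=18, alpha=0.7, label=sex)
    ax.set_xlabel("CSA (cm$^2$)")
    ax.set_ylabel("peak JVA (a.u.)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(outdir / "fig_association.png", dpi=110)
    plt.close(fig)
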