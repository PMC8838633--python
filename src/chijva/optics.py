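"""Layered Beer-Lambert rendering of near-infrared neck video.

The scene is a desk-scale lateral view of the neck: a horizontal segment of
the internal jugular vein (IJV) inferior to the neck midline, a band of
arterial (in-phase) pulsatility, a uniform sternocleidomastoid layer, and a
flexible reflectance calibration patch of known reflectance in the corner of
the field of view.

Per-pixel attenuation follows a modified Beer-Lambert model in reflection
geometry (light crosses each layer twice):

    A(x, y) = mu_blood * hb * L_blood(x, y; CSA) * D(depth)
              + mu_myo * 2 * scm(x, y) + background_mu

where ``L_blood`` is the two-pass chord length through the cylindrical
vessel, ``D(depth) = exp(-depth / delta)`` is a monotone-decreasing depth
sensitivity, and intensities are I = I0 * 10**(-A) plus sensor noise.

``mu_blood`` is set per participant so that the region-mean attenuation
slope versus CSA equals the participant's venous attenuation gain at the
reference hemoglobin and depth; hemoglobin and depth then modulate the
realized slope multiplicatively, which is exactly the pair of confounds the
imaging model is meant to expose.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import waveforms
from .cohort import ParticipantModel, VesselDynamics

__all__ = [
    "SceneModel",
    "FrameStack",
    "ReferenceSignals",
    "NoiseConfig",
    "depth_factor",
    "build_scene",
    "vessel_path_length",
    "vessel_mask",
    "attenuation_forward",
    "generate_ppg",
    "render_stack",
]

MU_MYO = 0.03          # a.u. per cm of sternocleidomastoid (one-pass)
BACKGROUND_MU = 0.417  # a.u., skin/baseline chromophores
DEPTH_DELTA = 1.0      # cm, depth-sensitivity scale
DEPTH_REF = 1.3        # cm, reference depth for gain normalization
NORM_WINDOW_CM = 0.8   # cm, nominal extraction-window height for gain normalization


@dataclass(frozen=True)
class SceneModel:
    """Static spatial layout of one neck scene (row 0 = superior)."""

    shape: tuple[int, int]
    pixel_pitch: float           # cm per pixel
    midline_row: int
    vessel_row: int              # vessel centroid row
    vessel_cols: tuple[int, int]  # half-open column range of the visible segment
    artery_rows: tuple[int, int]  # half-open row range of arterial band
    artery_amp: float            # a.u. attenuation modulation, in phase with PPG
    target: tuple[slice, slice]  # calibration patch (row slice, col slice)
    r_ref: float                 # known reflectance of the patch, in (0, 1]
    mu_blood: float              # a.u. per cm blood path per unit hemoglobin
    mu_myo: float = MU_MYO
    background_mu: float = BACKGROUND_MU
    depth_delta: float = DEPTH_DELTA
    scm_thickness: float = 1.0   # cm, uniform muscle layer

    def __post_init__(self) -> None:
        if not (0.0 < self.r_ref <= 1.0):
            raise ValueError("r_ref must lie in (0, 1]")

    def target_mask(self) -> np.ndarray:
        m = np.zeros(self.shape, dtype=bool)
        m[self.target] = True
        return m


@dataclass
class FrameStack:
    """T x H x W non-negative near-infrared intensity video."""

    data: np.ndarray
    fs: float
    illum_intensity: float = 1.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("stack must be T x H x W")
        if np.any(self.data < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]


@dataclass(frozen=True)
class ReferenceSignals:
    """Time-synchronized finger PPG and ECG R-spike times."""

    ppg: np.ndarray
    r_spike_times: np.ndarray
    fs: float


@dataclass(frozen=True)
class NoiseConfig:
    """Signal-dependent shot noise (variance = shot_scale * I) plus read noise."""

    shot_scale: float = 2e-6
    read_sd: float = 2e-3

    @classmethod
    def off(cls) -> "NoiseConfig":
        return cls(shot_scale=0.0, read_sd=0.0)


def depth_factor(depth: float, delta: float = DEPTH_DELTA) -> float:
    """Monotone-decreasing depth sensitivity D(depth) in (0, 1]."""
    if depth <= 0:
        raise ValueError("depth must be positive")
    return float(np.exp(-depth / delta))


def build_scene(
    participant: ParticipantModel,
    shape: tuple[int, int] = (64, 64),
    pixel_pitch: float = 0.05,
    vessel_length_cm: float = 1.0,
    artery_amp: float = 0.02,
    r_ref: float = 0.95,
    mu_blood: float | None = None,
    max_csa: float = 1.2,
) -> SceneModel:
    """Default scene geometry for one participant.

    The vessel segment is centered horizontally, aligned to the 4x4
    down-sampling grid, and placed in the inferior half; the arterial band
    sits between the midline and the vessel.  ``mu_blood`` defaults to the
    participant's venous gain normalized at reference depth/hemoglobin.
    """
    h, w = shape
    if h < 16 or w < 16:
        raise ValueError("scene must be at least 16 x 16 pixels")
    midline = h // 2
    vessel_row = int(round(0.75 * h))
    n_cols = max(4, 4 * round(vessel_length_cm / pixel_pitch / 4))
    c0 = 4 * ((w - n_cols) // 8)
    target_px = max(4, min(8, 4 * (w // 16)))
    if mu_blood is None:
        n_norm = max(1, round(NORM_WINDOW_CM / pixel_pitch))
        dlbar_dcsa = 2.0 / (pixel_pitch * n_norm)
        mu_blood = participant.jva_gain / (depth_factor(DEPTH_REF) * dlbar_dcsa)
    scene = SceneModel(
        shape=shape,
        pixel_pitch=pixel_pitch,
        midline_row=midline,
        vessel_row=vessel_row,
        vessel_cols=(c0, c0 + n_cols),
        artery_rows=(midline + 2, midline + 4),
        artery_amp=artery_amp,
        target=(slice(0, target_px), slice(0, target_px)),
        r_ref=r_ref,
        mu_blood=float(mu_blood),
        scm_thickness=participant.scm_thickness,
    )
    # Vessel must stay strictly inferior to the midline up to max_csa.
    r_px = np.sqrt(max_csa / np.pi) / pixel_pitch
    if scene.vessel_row - r_px <= midline:
        raise ValueError("vessel crosses the midline at the configured maximum CSA")
    return scene


def vessel_path_length(scene: SceneModel, csa: float) -> np.ndarray:
    """Two-pass blood path length (cm) per pixel for a cylindrical vessel."""
    if csa <= 0:
        raise ValueError("csa must be positive")
    h, w = scene.shape
    radius = np.sqrt(csa / np.pi)
    d = (np.arange(h) - scene.vessel_row) * scene.pixel_pitch
    chord = 2.0 * np.sqrt(np.clip(radius**2 - d**2, 0.0, None))
    L = np.zeros((h, w))
    c0, c1 = scene.vessel_cols
    L[:, c0:c1] = 2.0 * chord[:, None]
    return L


def vessel_mask(scene: SceneModel, csa: float) -> np.ndarray:
    """Boolean mask of pixels with nonzero blood path at the given CSA."""
    return vessel_path_length(scene, csa) > 0.0


def downsampled_vessel_mask(scene: SceneModel, csa: float, block: int = 4, coverage: float = 0.25) -> np.ndarray:
    """Ground-truth vessel mask on the block-down-sampled grid.

    A down-sampled pixel counts as vessel when at least ``coverage`` of its
    block overlaps the vessel support at the given CSA.
    """
    m = vessel_mask(scene, csa)
    h, w = m.shape
    hb, wb = h // block, w // block
    frac = m[: hb * block, : wb * block].reshape(hb, block, wb, block).mean(axis=(1, 3))
    return frac >= coverage


def attenuation_forward(scene: SceneModel, participant: ParticipantModel, csa_t: float) -> np.ndarray:
    """Per-pixel attenuation A(x, y) in a.u. at one instantaneous CSA."""
    blood = (
        scene.mu_blood
        * participant.hb_scale
        * vessel_path_length(scene, csa_t)
        * depth_factor(participant.ijv_depth, scene.depth_delta)
    )
    muscle = scene.mu_myo * 2.0 * scene.scm_thickness
    return blood + muscle + scene.background_mu


def generate_ppg(
    heart_rate: float,
    duration: float,
    fs: float,
    seed: int,
    jitter: float = 0.02,
    noise_sd: float = 0.01,
) -> ReferenceSignals:
    """Quasi-periodic arterial PPG with ECG R-spike times.

    R-spikes precede each systolic upstroke by a fixed pulse-transit phase
    offset; cycle lengths carry small fractional jitter.
    """
    if heart_rate <= 0 or duration <= 0 or fs <= 0:
        raise ValueError("heart_rate, duration and fs must be positive")
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    spikes = waveforms.beat_times(heart_rate, duration, seed, jitter=jitter)
    ppg = waveforms.ppg_series(t, spikes)
    if noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence((int(seed), 1)))
        ppg = ppg + noise_sd * rng.standard_normal(n)
    return ReferenceSignals(ppg=ppg, r_spike_times=spikes[spikes <= duration], fs=fs)


def render_stack(
    scene: SceneModel,
    participant: ParticipantModel,
    dynamics: VesselDynamics,
    signals: ReferenceSignals,
    noise_cfg: NoiseConfig | None = None,
    seed: int = 0,
    illum_intensity: float = 1.0,
) -> FrameStack:
    """Render the intensity video I = I0 * 10**(-A) for one acquisition.

    Calibration-patch pixels carry I = I0 * r_ref; arterial-band pixels
    modulate in phase with the PPG (in attenuation), vessel pixels
    anti-phase.  With ``noise_cfg=None`` the render is noise-free.
    """
    if signals.fs != dynamics.sample_rate:
        raise ValueError("dynamics and reference signals must share the sample rate")
    csa_series = dynamics.csa_series()
    n = len(csa_series)
    if len(signals.ppg) != n:
        raise ValueError("dynamics and reference signals must share the duration")
    h, w = scene.shape
    a0, a1 = scene.artery_rows
    c0, c1 = scene.vessel_cols
    muscle_bg = scene.mu_myo * 2.0 * scene.scm_thickness + scene.background_mu
    dfac = scene.mu_blood * participant.hb_scale * depth_factor(participant.ijv_depth, scene.depth_delta)
    ppg_unit = signals.ppg / max(np.abs(signals.ppg).max(), 1e-12)

    # Two-pass chord per (frame, row), broadcast across the vessel columns.
    radius = np.sqrt(csa_series / np.pi)
    d = (np.arange(h) - scene.vessel_row) * scene.pixel_pitch
    chords = 4.0 * np.sqrt(np.clip(radius[:, None] ** 2 - d[None, :] ** 2, 0.0, None))
    A = np.full((n, h, w), muscle_bg)
    A[:, :, c0:c1] += dfac * chords[:, :, None]
    A[:, a0:a1, c0:c1] += scene.artery_amp * (1.0 + ppg_unit[:, None, None])

    data = illum_intensity * 10.0 ** (-A)
    tmask = scene.target_mask()
    data[:, tmask] = illum_intensity * scene.r_ref

    if noise_cfg is not None and (noise_cfg.shot_scale > 0 or noise_cfg.read_sd > 0):
        rng = np.random.default_rng(np.random.SeedSequence((int(seed), 3)))
        sd = np.sqrt(noise_cfg.shot_scale * data + noise_cfg.read_sd**2)
        data = np.clip(data + sd * rng.standard_normal(data.shape), 1e-9, None)

    return FrameStack(
        data=data,
        fs=dynamics.sample_rate,
        illum_intensity=illum_intensity,
        metadata={"seed": int(seed), "participant": participant.id},
    )
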