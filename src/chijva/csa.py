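"""Simulated ultrasound measurement of jugular cross-sectional area.

The measurement stage reproduces the frame-selection and max-CSA logic of
cine-loop ultrasonography: a ~5-s loop at ~23 fps, the frame immediately
following each ECG R-spike (approximately the c-wave of the jugular venous
pulse), and the maximum area across the ~5 selected cardiac cycles to
minimize respiratory variability.  Speckle-image ellipse fitting is replaced
by ground truth plus Gaussian operator noise — an explicit simplification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import waveforms
from .cohort import ConditionLevel, ParticipantModel, true_csa

__all__ = [
    "CineLoop",
    "CsaMeasurement",
    "simulate_cine_loop",
    "select_post_rspike_frames",
    "measure_csa",
]


@dataclass(frozen=True)
class CineLoop:
    """Per-frame ground-truth CSA (cm**2) with synchronized R-spike times."""

    csa_true: np.ndarray
    fps: float
    r_spike_times: np.ndarray
    duration: float


@dataclass(frozen=True)
class CsaMeasurement:
    value: float          # cm**2
    n_cycles_used: int

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError("measured CSA must be positive")


def simulate_cine_loop(
    participant: ParticipantModel,
    cond: ConditionLevel,
    seed: int,
    duration: float = 5.0,
    fps: float = 23.0,
    cardiac_amp: float = 0.08,
    resp_amp: float = 0.05,
    jitter: float = 0.02,
) -> CineLoop:
    """Ground-truth cine loop at one condition level.

    Uses the same venous waveform model as the optical renderer, so the
    sample just after each R-spike sits on the c-wave.
    """
    n = int(round(duration * fps))
    t = np.arange(n) / fps
    spikes = waveforms.beat_times(participant.heart_rate, duration, seed, jitter=jitter)
    cardiac = cardiac_amp * waveforms.venous_series(t, spikes)
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 2)))
    phase = rng.uniform(0.0, 2.0 * np.pi)
    resp = resp_amp * np.sin(2.0 * np.pi * participant.resp_rate / 60.0 * t + phase)
    series = true_csa(participant, cond) * (1.0 + cardiac + resp)
    return CineLoop(
        csa_true=series,
        fps=fps,
        r_spike_times=spikes[spikes <= duration],
        duration=duration,
    )


def select_post_rspike_frames(loop: CineLoop) -> np.ndarray:
    """Index of the frame immediately following each R-spike.

    ``floor(s * fps) + 1`` for spike time ``s``; spikes whose following frame
    falls beyond the loop are dropped, duplicates removed.
    """
    spikes = np.asarray(loop.r_spike_times, dtype=float)
    if spikes.size == 0:
        raise ValueError("cine loop contains no R-spikes")
    idx = np.floor(spikes * loop.fps).astype(int) + 1
    idx = np.unique(idx[idx < len(loop.csa_true)])
    if idx.size == 0:
        raise ValueError("no post-R-spike frame falls inside the loop")
    return idx


def measure_csa(loop: CineLoop, noise_sd: float = 0.02, seed: int = 0) -> CsaMeasurement:
    """Maximum CSA over the post-R-spike frames, with operator noise.

    Noise is Gaussian per selected frame (truncated to keep areas positive);
    the measurement is monotone non-decreasing in every per-frame true CSA.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    idx = select_post_rspike_frames(loop)
    vals = loop.csa_true[idx].astype(float)
    if noise_sd > 0:
        rng = np.random.default_rng(int(seed))
        vals = np.maximum(vals + noise_sd * rng.standard_normal(len(idx)), 1e-6)
    return CsaMeasurement(value=float(vals.max()), n_cycles_used=int(len(idx)))
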