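"""Cardiac cycle timing and canonical arterial/venous pulse shapes.

Both the optical renderer and the vessel-dynamics generator need the same
beat clock so that the jugular volume waveform is deterministically
anti-phase with the finger photoplethysmogram (PPG).  The shapes are
phase-locked to the ECG R-spike (phase 0 of each cycle):

* arterial PPG: systolic peak near phase 0.30 (a fixed pulse-transit delay
  after the R-spike) with a dicrotic bump near phase 0.55;
* jugular venous volume: small c-wave bump just after the R-spike
  (phase ~0.08), deep x-descent coinciding with the systolic PPG peak,
  and a v-wave during late diastole (phase ~0.72).

The x-descent/systole overlap is what makes venous pixels anticorrelate
with the PPG, which is the localization cue used downstream.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "beat_times",
    "cycle_phase",
    "ppg_shape",
    "venous_shape",
    "ppg_series",
    "venous_series",
]


def _bump(phi: np.ndarray, center: float, width: float) -> np.ndarray:
    """Periodic Gaussian bump on phase in [0, 1)."""
    d = (phi - center + 0.5) % 1.0 - 0.5
    return np.exp(-0.5 * (d / width) ** 2)


def ppg_shape(phi: np.ndarray) -> np.ndarray:
    """Raw (unnormalized) arterial PPG over cycle phase."""
    phi = np.asarray(phi, dtype=float)
    return _bump(phi, 0.30, 0.12) + 0.35 * _bump(phi, 0.55, 0.08)


def venous_shape(phi: np.ndarray) -> np.ndarray:
    """Raw jugular venous volume modulation over cycle phase (a/c/v waves)."""
    phi = np.asarray(phi, dtype=float)
    return (
        0.35 * _bump(phi, 0.08, 0.05)   # c-wave
        - 1.00 * _bump(phi, 0.33, 0.12)  # x-descent
        + 0.80 * _bump(phi, 0.72, 0.12)  # v-wave
    )


# Normalization constants (zero mean, unit peak magnitude) computed on a
# dense phase grid once at import.
_GRID = np.linspace(0.0, 1.0, 4096, endpoint=False)
_PPG_MEAN = float(ppg_shape(_GRID).mean())
_PPG_SCALE = float(np.abs(ppg_shape(_GRID) - _PPG_MEAN).max())
_VEN_MEAN = float(venous_shape(_GRID).mean())
_VEN_SCALE = float(np.abs(venous_shape(_GRID) - _VEN_MEAN).max())


def beat_times(heart_rate: float, duration: float, seed: int, jitter: float = 0.02) -> np.ndarray:
    """R-spike times covering [0, duration] with fractional cycle-length jitter.

    The first spike is at t=0 and spikes are generated past ``duration`` so
    every sample in the record falls inside a defined cycle.
    """
    if heart_rate <= 0 or duration <= 0:
        raise ValueError("heart_rate and duration must be positive")
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 0)))
    mean_t = 60.0 / heart_rate
    n = int(np.ceil(duration / mean_t)) + 3
    cycles = mean_t * (1.0 + jitter * rng.standard_normal(n))
    cycles = np.clip(cycles, 0.5 * mean_t, 1.5 * mean_t)
    return np.concatenate([[0.0], np.cumsum(cycles)])


def cycle_phase(t: np.ndarray, spikes: np.ndarray) -> np.ndarray:
    """Phase in [0, 1) of each time point within its enclosing cardiac cycle."""
    t = np.asarray(t, dtype=float)
    idx = np.clip(np.searchsorted(spikes, t, side="right") - 1, 0, len(spikes) - 2)
    return (t - spikes[idx]) / (spikes[idx + 1] - spikes[idx])


def ppg_series(t: np.ndarray, spikes: np.ndarray) -> np.ndarray:
    """Zero-mean, unit-peak arterial PPG sampled at times ``t``."""
    return (ppg_shape(cycle_phase(t, spikes)) - _PPG_MEAN) / _PPG_SCALE


def venous_series(t: np.ndarray, spikes: np.ndarray) -> np.ndarray:
    """Zero-mean, unit-peak jugular venous volume modulation at times ``t``."""
    return (venous_shape(cycle_phase(t, spikes)) - _VEN_MEAN) / _VEN_SCALE
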