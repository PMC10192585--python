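"""Evoked potentials: condition averages, difference waves, component measures.

Component conventions follow the feedback-monitoring literature: an early
fronto-central negativity (oNe, 200-300 ms), an error positivity (oPe,
450-600 ms) and a later interaction potential (Ip, ~700 ms), all measured
on the error-minus-correct difference at fronto-central sites.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .containers import Epochs

logger = logging.getLogger(__name__)

#: default fronto-central measurement set (the montage has no Fz/F2; F1 is
#: the closest frontal site available)
FRONTOCENTRAL = ("F1", "FCz", "FC1", "FC2", "Cz", "C1")

DEFAULT_WINDOWS = {
    "oNe": (0.20, 0.30),
    "oPe": (0.45, 0.60),
    "Ip": (0.65, 0.75),
    "P300": (0.25, 0.50),
}
#: measurement polarity per component (+1 positive-going, -1 negative-going)
POLARITY = {"oNe": -1, "oPe": +1, "Ip": -1, "iCNV": -1, "P300": +1}


@dataclass
class EvokedSet:
    """Per-condition averages of one subject: condition -> (channels, times)."""

    averages: dict[str, np.ndarray]
    times: np.ndarray
    ch_names: tuple[str, ...]
    n_epochs: dict[str, int]
    lock_kind: str = ""
    low_n: dict[str, bool] = field(default_factory=dict)


@dataclass
class ComponentMeasure:
    name: str
    window_s: tuple[float, float]
    channels: tuple[str, ...]
    amplitude: float  # signed extremum of the channel mean, uV
    latency_s: float
    mean_amplitude: float  # window-mean alternative
    flagged: bool = False


def average_evoked(epochs: Epochs, by: str = "condition",
                   min_epochs: int = 5, lock_kind: str = "") -> EvokedSet:
    """Arithmetic mean over epochs for each level of a metadata column."""
    if by not in epochs.metadata.columns:
        raise ValueError(f"metadata has no column {by!r}")
    averages, counts, low_n = {}, {}, {}
    for level, idx in epochs.metadata.groupby(by, observed=True).groups.items():
        sub = epochs.data[np.asarray(idx)]
        if sub.shape[0] == 0:
            raise ValueError(f"empty cell for {by}={level}")
        averages[str(level)] = sub.mean(axis=0)
        counts[str(level)] = sub.shape[0]
        low_n[str(level)] = sub.shape[0] < min_epochs
        if low_n[str(level)]:
            logger.warning("cell %s=%s averaged from only %d epochs",
                           by, level, sub.shape[0])
    return EvokedSet(averages, epochs.times, epochs.ch_names, counts,
                     lock_kind, low_n)


def difference_wave(evoked_error: np.ndarray, evoked_correct: np.ndarray) -> np.ndarray:
    """Pointwise error-minus-correct difference."""
    a = np.asarray(evoked_error)
    b = np.asarray(evoked_correct)
    if a.shape != b.shape:
        raise ValueError("evoked grids do not match")
    return a - b


def measure_component(data: np.ndarray, times: np.ndarray,
                      ch_names: tuple[str, ...], name: str,
                      window_s: tuple[float, float] | None = None,
                      channels: tuple[str, ...] = FRONTOCENTRAL) -> ComponentMeasure:
    """Signed-extremum amplitude and latency of a component.

    The channel-mean waveform over the requested sites is searched inside
    the window; positive components take the maximum, negative ones the
    minimum.  A flat signal yields amplitude 0 at the window start; a
    wrong-signed extremum is flagged.
    """
    window_s = window_s or DEFAULT_WINDOWS[name]
    pol = POLARITY.get(name, +1)
    missing = [c for c in channels if c not in ch_names]
    if missing:
        raise ValueError(f"channels not in data: {missing}")
    tsel = (times >= window_s[0] - 1e-9) & (times <= window_s[1] + 1e-9)
    if not tsel.any():
        raise ValueError(f"window {window_s} outside the epoch span")
    picks = [ch_names.index(c) for c in channels]
    wave = data[picks].mean(axis=0)[tsel]
    tw = times[tsel]
    idx = int(np.argmax(wave)) if pol > 0 else int(np.argmin(wave))
    amplitude = float(wave[idx])
    flagged = amplitude * pol < 0  # extremum has the wrong sign
    if np.allclose(wave, wave[0]):
        idx, amplitude, flagged = 0, float(wave[0]), False
    return ComponentMeasure(name, window_s, tuple(channels), amplitude,
                            float(tw[idx]), float(wave.mean()), flagged)
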