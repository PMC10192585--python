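"""In-memory containers shared by every pipeline stage."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .montage import MontageLayout

#: recognised event kinds
EVENT_KINDS = ("flash", "cue", "movement_onset", "feedback_onset", "rest_onset")
#: recognised condition labels
CONDITIONS = ("AO", "AAO", "BCI_correct", "BCI_error", "AE", "REST")


@dataclass
class RawRecording:
    """Continuous multichannel EEG in microvolts.

    ``data`` is (n_channels, n_samples); channel order follows ``montage``.
    """

    data: np.ndarray
    sfreq: float
    montage: MontageLayout
    reference: str = "monopolar"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.data.shape[0] != len(self.montage):
            raise ValueError(
                f"data has {self.data.shape[0]} rows but montage has "
                f"{len(self.montage)} channels"
            )
        if self.sfreq <= 0:
            raise ValueError("sfreq must be positive")
        if np.isnan(self.data).any():
            raise ValueError("recording contains NaNs")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sfreq

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sfreq

    def copy_with(self, data: np.ndarray, reference: str | None = None) -> "RawRecording":
        return replace(self, data=data, reference=reference or self.reference)


@dataclass
class EventSchedule:
    """Typed, time-stamped events backed by a DataFrame.

    Columns: onset_s (float), kind, finger (Int64, nullable), is_target
    (boolean, nullable), condition, trial_index (Int64, nullable).
    """

    events: pd.DataFrame

    COLUMNS = ("onset_s", "kind", "finger", "is_target", "condition", "trial_index")

    def __post_init__(self) -> None:
        ev = self.events
        missing = set(self.COLUMNS) - set(ev.columns)
        if missing:
            raise ValueError(f"events frame missing columns {sorted(missing)}")
        onset = ev["onset_s"].to_numpy(dtype=float)
        if len(onset) and not np.all(np.diff(onset) > 0):
            raise ValueError("event onsets must be strictly increasing")
        bad_kind = set(ev["kind"]) - set(EVENT_KINDS)
        if bad_kind:
            raise ValueError(f"unknown event kinds {sorted(bad_kind)}")
        bad_cond = set(ev["condition"].dropna()) - set(CONDITIONS)
        if bad_cond:
            raise ValueError(f"unknown conditions {sorted(bad_cond)}")

    def __len__(self) -> int:
        return len(self.events)

    def of_kind(self, kind: str) -> pd.DataFrame:
        return self.events[self.events["kind"] == kind]

    @property
    def end(self) -> float:
        return float(self.events["onset_s"].max()) if len(self.events) else 0.0

    @staticmethod
    def from_records(records: list[dict]) -> "EventSchedule":
        df = pd.DataFrame.from_records(records, columns=list(EventSchedule.COLUMNS))
        df["finger"] = df["finger"].astype("Int64")
        df["trial_index"] = df["trial_index"].astype("Int64")
        df["is_target"] = df["is_target"].astype("boolean")
        return EventSchedule(df)


@dataclass
class Epochs:
    """Event-locked data segments: (n_epochs, n_channels, n_times)."""

    data: np.ndarray
    times: np.ndarray
    sfreq: float
    metadata: pd.DataFrame = field(default_factory=pd.DataFrame)
    ch_names: tuple[str, ...] = ()
    baseline_interval: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.times = np.asarray(self.times, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("epoch data must be 3-D")
        if self.data.shape[2] != len(self.times):
            raise ValueError("times length must match last data axis")
        steps = np.diff(self.times)
        if len(steps) and not (
            np.all(steps > 0) and np.allclose(steps, 1.0 / self.sfreq, rtol=1e-6)
        ):
            raise ValueError("times must increase uniformly at 1/sfreq")
        if len(self.metadata) and len(self.metadata) != self.data.shape[0]:
            raise ValueError("metadata length must match epoch count")

    def __len__(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    def select(self, mask: np.ndarray) -> "Epochs":
        mask = np.asarray(mask)
        md = self.metadata.iloc[mask].reset_index(drop=True) if len(self.metadata) else self.metadata
        return Epochs(self.data[mask], self.times, self.sfreq, md,
                      self.ch_names, self.baseline_interval)

    def crop(self, tmin: float, tmax: float) -> "Epochs":
        sel = (self.times >= tmin - 1e-9) & (self.times <= tmax + 1e-9)
        return Epochs(self.data[:, :, sel], self.times[sel], self.sfreq,
                      self.metadata, self.ch_names, self.baseline_interval)
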