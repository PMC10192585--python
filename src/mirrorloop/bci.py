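"""Offline P300-speller decoding and feedback accounting.

Flash-locked epochs are reduced to windowed, decimated amplitude features
over a centro-parietal channel subset; a shrinkage-regularized linear
discriminant scores each flash as target-like or not; a trial's finger is
the one whose flashes score highest on average.  The feedback stage
reproduces the online loop's deliberate falsification: a fixed number of
trials receive a randomly chosen wrong finger, bounding attainable feedback
accuracy at (n_trials - n_errors) / n_trials.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import GroupKFold

from .containers import Epochs

logger = logging.getLogger(__name__)

#: default centro-parietal feature channels
FEATURE_CHANNELS = ("Cz", "C1", "C2", "CPz", "CP1", "CP2", "CP3", "CP4",
                    "Pz", "P1", "P2", "POz")


@dataclass
class FlashFeatureSet:
    X: np.ndarray  # flashes x features
    y: np.ndarray  # 1 = target flash
    trial_index: np.ndarray
    finger: np.ndarray

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.X)):
            raise ValueError("features must be finite")


@dataclass
class SessionResult:
    trials: pd.DataFrame  # target, chosen, feedback, forced_error per trial

    def __post_init__(self) -> None:
        t = self.trials
        forced = t["forced_error"].to_numpy(dtype=bool)
        same = t["feedback"].to_numpy() == t["chosen"].to_numpy()
        if np.any(same[forced]) or np.any(~same[~forced]):
            raise ValueError("feedback must differ from the chosen finger "
                             "exactly on forced-error trials")

    @property
    def accuracy(self) -> float:
        return float((self.trials["feedback"] == self.trials["target"]).mean())


def extract_flash_features(flash_epochs: Epochs,
                           window: tuple[float, float] = (0.0, 0.8),
                           decim: int = 10,
                           channels: tuple[str, ...] = FEATURE_CHANNELS) -> FlashFeatureSet:
    """Block-averaged post-flash amplitudes, flattened channel x time."""
    lo, hi = window
    step = 1.0 / flash_epochs.sfreq
    # hi is an exclusive bound: the last required sample is hi - step
    if lo < flash_epochs.times[0] - 1e-9 or hi - step > flash_epochs.times[-1] + 1e-9:
        raise ValueError(f"window {window} beyond the flash epoch span")
    picks = [flash_epochs.ch_names.index(c) for c in channels]
    sel = (flash_epochs.times >= lo - 1e-9) & (flash_epochs.times < hi - 1e-9)
    data = flash_epochs.data[:, picks][:, :, sel]
    n_ep, n_ch, n_t = data.shape
    n_blocks = n_t // decim
    data = data[:, :, : n_blocks * decim].reshape(n_ep, n_ch, n_blocks, decim)
    X = data.mean(axis=3).reshape(n_ep, n_ch * n_blocks)
    md = flash_epochs.metadata
    y = md["is_target"].astype(bool).to_numpy().astype(int)
    return FlashFeatureSet(X, y,
                           md["trial_index"].to_numpy(dtype=int),
                           md["finger"].to_numpy(dtype=int))


class FlashDecoder(BaseEstimator, ClassifierMixin):
    """Shrinkage LDA over flash features; higher score = more target-like."""

    def __init__(self, shrinkage: str | float = "auto"):
        self.shrinkage = shrinkage

    def fit(self, X, y) -> "FlashDecoder":
        X = np.asarray(X)
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise ValueError("both target and non-target flashes are required")
        if X.shape[0] <= 2:
            raise ValueError("need more than 2 flashes to fit")
        self._lda = LinearDiscriminantAnalysis(
            solver="lsqr", shrinkage=self.shrinkage)
        self._lda.fit(X, y)
        self.coef_ = self._lda.coef_.ravel()
        self.intercept_ = float(self._lda.intercept_[0])
        return self

    def decision_function(self, X) -> np.ndarray:
        return np.asarray(X) @ self.coef_ + self.intercept_

    def predict(self, X) -> np.ndarray:
        return (self.decision_function(X) > 0).astype(int)


def fit_lda(X: np.ndarray, y: np.ndarray,
            shrinkage: str | float = "auto") -> FlashDecoder:
    return FlashDecoder(shrinkage=shrinkage).fit(X, y)


def decide_trial(scores: np.ndarray, fingers: np.ndarray,
                 n_fingers: int) -> int:
    """Chosen finger = argmax of the mean flash score; ties -> lowest index."""
    means = np.full(n_fingers, -np.inf)
    for f in range(n_fingers):
        m = fingers == f
        if m.any():
            means[f] = scores[m].mean()
        else:
            logger.warning("finger %d has no flashes in this trial", f)
    best = float(means.max())
    winners = np.flatnonzero(np.isclose(means, best))
    if len(winners) > 1:
        logger.info("tie between fingers %s; choosing lowest index", winners)
    return int(winners[0])


def decode_session(features: FlashFeatureSet, n_fingers: int,
                   n_folds: int = 5, shrinkage: str | float = "auto") -> np.ndarray:
    """Cross-validated within-session decoding: each trial is scored by a
    model trained on the other folds' trials.  Returns the chosen finger
    per trial."""
    trials = np.unique(features.trial_index)
    decisions = np.full(trials.max() + 1, -1, dtype=int)
    gkf = GroupKFold(n_splits=n_folds)
    for train, test in gkf.split(features.X, features.y, groups=features.trial_index):
        model = fit_lda(features.X[train], features.y[train], shrinkage)
        scores = model.decision_function(features.X[test])
        for trial in np.unique(features.trial_index[test]):
            m = features.trial_index[test] == trial
            decisions[trial] = decide_trial(scores[m],
                                            features.finger[test][m], n_fingers)
    return decisions[trials]


def inject_errors(decisions: np.ndarray, targets: np.ndarray,
                  n_errors: int = 15, n_fingers: int = 4,
                  seed: int | np.random.Generator = 0) -> SessionResult:
    """Forced-error feedback: on ``n_errors`` uniformly chosen trials the
    feedback finger is drawn uniformly among the other fingers."""
    if n_fingers < 2:
        raise ValueError("need at least 2 fingers")
    decisions = np.asarray(decisions, dtype=int)
    n_trials = len(decisions)
    if n_errors > n_trials:
        raise ValueError("n_errors cannot exceed the number of trials")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    forced = np.zeros(n_trials, dtype=bool)
    forced[rng.choice(n_trials, size=n_errors, replace=False)] = True
    feedback = decisions.copy()
    for i in np.flatnonzero(forced):
        others = [f for f in range(n_fingers) if f != decisions[i]]
        feedback[i] = rng.choice(others)
    frame = pd.DataFrame(dict(trial=np.arange(n_trials), target=targets,
                              chosen=decisions, feedback=feedback,
                              forced_error=forced))
    return SessionResult(frame)


def session_accuracy(result: SessionResult) -> float:
    if len(result.trials) == 0:
        raise ValueError("empty session")
    return result.accuracy
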