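"""Two-class common spatial patterns with covariance cleaning.

The active class is observation of a (virtual) movement, the rest class a
motionless hand.  Filters solve the generalized eigenproblem
``C_active w = lambda (C_active + C_rest) w``; eigenvalues therefore live in
[0, 1] and measure the fraction of composite variance each component carries
in the active state.  Components whose scalp patterns are not concentrated
over the sensorimotor rows are discarded, which suppresses the occipital
alpha confound.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import linalg, signal as sps
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import Epochs
from .montage import MontageLayout

logger = logging.getLogger(__name__)


@dataclass
class BandSpec:
    """A (possibly subject-specific) analysis frequency band."""

    name: str  # mu | beta | ers
    range_hz: tuple[float, float]
    subject_specific: bool = False

    def validate(self, search_range: tuple[float, float] | None = None) -> None:
        lo, hi = self.range_hz
        if not lo < hi:
            raise ValueError("BandSpec.range_hz must be ordered low < high")
        if search_range is not None:
            if lo < search_range[0] - 1e-9 or hi > search_range[1] + 1e-9:
                raise ValueError(
                    f"band {self.range_hz} outside search range {search_range}")


@dataclass
class CovarianceSet:
    cov_active: np.ndarray
    cov_rest: np.ndarray
    n_epochs_used: tuple[int, int]
    rejected_epoch_indices: tuple[list[int], list[int]]


def epoch_covariances(epochs: Epochs | np.ndarray, normalize: bool = True) -> list[np.ndarray]:
    """Per-epoch spatial covariance of mean-centered data."""
    data = epochs.data if isinstance(epochs, Epochs) else np.asarray(epochs)
    if data.shape[0] < 2:
        raise ValueError("need at least 2 epochs")
    covs = []
    for ep in data:
        if ep.shape[1] < ep.shape[0]:
            logger.warning("epoch shorter than channel count: rank-deficient")
        x = ep - ep.mean(axis=1, keepdims=True)
        c = x @ x.T / x.shape[1]
        if normalize:
            tr = np.trace(c)
            if tr > 0:
                c = c / tr
        covs.append(c)
    return covs


def clean_covariances(per_epoch_covs: list[np.ndarray],
                      max_reject_frac: float = 0.2,
                      z_thresh: float = 2.5) -> tuple[np.ndarray, list[int]]:
    """Iteratively drop epochs whose covariance is a Frobenius outlier.

    At each step the epoch farthest (Frobenius norm) from the current mean
    covariance is removed if its distance is a robust outlier (z-score vs
    the median/MAD of all distances exceeds ``z_thresh``), until the
    rejection cap is hit.  Returns the mean covariance of the survivors and
    the rejected indices.
    """
    n = len(per_epoch_covs)
    if n < 5:
        raise ValueError("need at least 5 epochs to clean covariances")
    covs = np.array(per_epoch_covs)
    keep = np.ones(n, dtype=bool)
    max_reject = int(np.ceil(max_reject_frac * n))
    rejected: list[int] = []
    while len(rejected) < max_reject:
        if keep.sum() <= 3:
            logger.warning("covariance cleaning stopped: would leave < 3 epochs")
            break
        mean_cov = covs[keep].mean(axis=0)
        d = np.linalg.norm(covs - mean_cov, axis=(1, 2))
        d_keep = d[keep]
        med = np.median(d_keep)
        mad = np.median(np.abs(d_keep - med))
        sigma = 1.4826 * mad
        if sigma <= 0:
            break
        z = (d - med) / sigma
        z[~keep] = -np.inf
        worst = int(np.argmax(z))
        if z[worst] <= z_thresh:
            break
        keep[worst] = False
        rejected.append(worst)
    return covs[keep].mean(axis=0), sorted(rejected)


def _check_symmetric(c: np.ndarray, name: str) -> None:
    if not np.allclose(c, c.T, atol=1e-8):
        raise ValueError(f"{name} covariance is not symmetric")


class CSP(BaseEstimator, TransformerMixin):
    """Common spatial pattern transformer (active vs rest).

    Parameters
    ----------
    n_components : number of candidate components kept (half from each tail
        of the eigenvalue spectrum).
    shrinkage : per-class shrinkage toward the scaled identity, as a fraction
        of the mean eigenvalue, applied before the eigenproblem.
    clean : whether to run the covariance-cleaning step on per-epoch
        covariances before averaging.

    Fitted attributes: ``filters_`` (components x channels, all of them),
    ``patterns_`` (channels x components), ``eigenvalues_`` sorted
    descending, ``candidates_`` (indices of the retained tails) and, after
    :meth:`select_central`, ``selected_``.
    """

    def __init__(self, n_components: int = 6, shrinkage: float = 1e-3,
                 clean: bool = True, max_reject_frac: float = 0.2,
                 z_thresh: float = 2.5):
        self.n_components = n_components
        self.shrinkage = shrinkage
        self.clean = clean
        self.max_reject_frac = max_reject_frac
        self.z_thresh = z_thresh

    # -- fitting -----------------------------------------------------------
    def fit(self, X, y) -> "CSP":
        """Fit from epochs (n_epochs, n_channels, n_times) and binary labels
        (1 = active, 0 = rest)."""
        X = np.asarray(X)
        y = np.asarray(y)
        covset = self._class_covariances(X, y)
        self.covariances_ = covset
        self._fit_from_covariances(covset.cov_active, covset.cov_rest)
        return self

    def fit_epochs(self, X_active: np.ndarray, X_rest: np.ndarray) -> "CSP":
        """Fit from two epoch arrays; epoch lengths may differ per class."""
        covset = self._class_covariances_from(
            {"active": np.asarray(X_active), "rest": np.asarray(X_rest)})
        self.covariances_ = covset
        self._fit_from_covariances(covset.cov_active, covset.cov_rest)
        return self

    def _class_covariances(self, X: np.ndarray, y: np.ndarray) -> CovarianceSet:
        return self._class_covariances_from(
            {"active": X[y == 1], "rest": X[y == 0]})

    def _class_covariances_from(self, classes: dict[str, np.ndarray]) -> CovarianceSet:
        out = {}
        rejected = {}
        for cls in ("active", "rest"):
            covs = epoch_covariances(classes[cls], normalize=True)
            if self.clean and len(covs) >= 5:
                mean_cov, rej = clean_covariances(
                    covs, self.max_reject_frac, self.z_thresh)
            else:
                mean_cov, rej = np.mean(covs, axis=0), []
            out[cls] = (mean_cov, len(covs) - len(rej))
            rejected[cls] = rej
        return CovarianceSet(out["active"][0], out["rest"][0],
                             (out["active"][1], out["rest"][1]),
                             (rejected["active"], rejected["rest"]))

    def fit_from_covariances(self, cov_active: np.ndarray,
                             cov_rest: np.ndarray) -> "CSP":
        self._fit_from_covariances(cov_active, cov_rest)
        return self

    def _fit_from_covariances(self, ca: np.ndarray, cr: np.ndarray) -> None:
        _check_symmetric(ca, "active")
        _check_symmetric(cr, "rest")
        ca = self._shrink(ca)
        cr = self._shrink(cr)
        evals, evecs = linalg.eigh(ca, ca + cr)
        order = np.argsort(evals)[::-1]
        evals = np.clip(evals[order], 0.0, 1.0)
        W = evecs[:, order].T  # components x channels
        A = np.linalg.inv(W)  # channels x components
        self.filters_ = W
        self.patterns_ = A
        self.eigenvalues_ = evals
        k = self.n_components // 2
        n = len(evals)
        self.candidates_ = list(range(k)) + list(range(n - (self.n_components - k), n))
        self.selected_ = list(self.candidates_)

    def _shrink(self, c: np.ndarray) -> np.ndarray:
        mu = np.trace(c) / c.shape[0]
        return (1 - self.shrinkage) * c + self.shrinkage * mu * np.eye(c.shape[0])

    # -- component selection ----------------------------------------------
    def central_fractions(self, montage: MontageLayout) -> np.ndarray:
        mask = montage.central_mask()
        w = np.abs(self.patterns_)
        return w[mask].sum(axis=0) / w.sum(axis=0)

    def select_central(self, montage: MontageLayout,
                       min_central_frac: float = 0.6) -> "CSP":
        """Keep only candidates whose pattern weight concentrates over the
        sensorimotor (FC/C/CP) rows; fix the sign convention so the largest
        central weight of each pattern is positive."""
        frac = self.central_fractions(montage)
        selected = [i for i in self.candidates_ if frac[i] >= min_central_frac]
        if not selected:
            raise ValueError(
                "no CSP component passed the central-pattern criterion; "
                "review min_central_frac or the montage central set")
        mask = montage.central_mask()
        for i in selected:
            central_w = self.patterns_[mask, i]
            if central_w[np.argmax(np.abs(central_w))] < 0:
                self.patterns_[:, i] *= -1
                self.filters_[i] *= -1
        self.selected_ = selected
        return self

    # -- application -------------------------------------------------------
    def transform(self, X) -> np.ndarray:
        """Project epochs onto the selected components."""
        X = np.asarray(X)
        W = self.filters_[self.selected_]
        if X.shape[-2] != W.shape[1]:
            raise ValueError(
                f"epochs have {X.shape[-2]} channels, filters expect {W.shape[1]}")
        return np.einsum("kc,ect->ekt", W, X)

    def transform_epochs(self, epochs: Epochs) -> Epochs:
        comp = self.transform(epochs.data)
        names = tuple(f"csp{i}" for i in self.selected_)
        return Epochs(comp, epochs.times, epochs.sfreq, epochs.metadata, names)


def fit_csp(cov_active: np.ndarray, cov_rest: np.ndarray,
            n_components: int = 6, shrinkage: float = 1e-3) -> CSP:
    """Functional wrapper: fit a :class:`CSP` from class covariances."""
    return CSP(n_components=n_components,
               shrinkage=shrinkage).fit_from_covariances(cov_active, cov_rest)


def apply_csp(model: CSP, epochs: Epochs) -> Epochs:
    return model.transform_epochs(epochs)


def select_central(model: CSP, montage: MontageLayout,
                   min_central_frac: float = 0.6) -> CSP:
    return model.select_central(montage, min_central_frac)


def bandpass_epochs(epochs: Epochs, band: tuple[float, float]) -> Epochs:
    """Zero-phase 4th-order Butterworth band-pass applied per epoch."""
    sos = sps.butter(4, band, btype="bandpass", fs=epochs.sfreq, output="sos")
    data = sps.sosfiltfilt(sos, epochs.data, axis=2)
    return Epochs(data, epochs.times, epochs.sfreq, epochs.metadata,
                  epochs.ch_names, epochs.baseline_interval)


def select_subject_band(erds_map: np.ndarray, freqs: np.ndarray,
                        times: np.ndarray, search_range: tuple[float, float],
                        name: str = "mu", min_width_hz: float = 2.0,
                        window_s: tuple[float, float] = (0.0, 1.5),
                        depth_frac: float = 0.5) -> BandSpec:
    """Automated surrogate for by-eye band selection on execution trials.

    ``erds_map`` is a (frequencies x times) ERD/S map in dB.  The average
    ERD over the post-onset window is profiled across frequency; the band is
    the maximal contiguous set of frequencies at least ``depth_frac`` as
    deep as the deepest one, clipped to the search range and widened to the
    minimum width if needed.  A flat or ERS-only profile falls back to the
    full search range.
    """
    freqs = np.asarray(freqs, dtype=float)
    in_range = (freqs >= search_range[0] - 1e-9) & (freqs <= search_range[1] + 1e-9)
    tsel = (times >= window_s[0]) & (times <= window_s[1])
    profile = erds_map[:, tsel].mean(axis=1)
    profile = np.where(in_range, profile, np.inf)
    if not np.any(profile[in_range] < 0):
        logger.warning("no ERD found in %s search range; falling back to %s",
                       name, search_range)
        return BandSpec(name, search_range, subject_specific=False)
    peak_idx = int(np.argmin(profile))
    peak_depth = profile[peak_idx]
    deep = profile <= depth_frac * peak_depth  # both negative
    lo = peak_idx
    while lo > 0 and deep[lo - 1]:
        lo -= 1
    hi = peak_idx
    while hi < len(freqs) - 1 and deep[hi + 1]:
        hi += 1
    f_lo, f_hi = freqs[lo], freqs[hi]
    if f_hi - f_lo < min_width_hz:
        pad = (min_width_hz - (f_hi - f_lo)) / 2
        f_lo, f_hi = f_lo - pad, f_hi + pad
    f_lo = max(f_lo, search_range[0])
    f_hi = min(f_hi, search_range[1])
    return BandSpec(name, (float(f_lo), float(f_hi)), subject_specific=True)
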