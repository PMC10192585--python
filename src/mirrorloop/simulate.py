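"""Synthetic EEG cohorts with known sensorimotor-rhythm and ErrP structure.

The generator emulates the two-task study design: a P300-speller session in
which virtual finger flexions are shown as feedback (with a fixed number of
deliberately falsified feedback trials), and a passive observation session in
which half of the demonstrated movements are announced by a cue one second
before onset.  Signals are built by linear forward mixing: every source has
an isotropic Gaussian scalp pattern (on great-circle distance), a narrowband
or transient time-course, and an amplitude envelope carrying the configured
ERD/ERS dynamics.  Background activity is 1/f noise, per channel plus a
shared volume-conducted term; an occipital alpha generator and optional
blink/muscle artifact sources act as confounds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import signal as sps

from .containers import EventSchedule, RawRecording
from .montage import MontageLayout, standard_montage

# conditions whose mu envelope starts declining before movement onset
_ANTICIPATED = {"AAO", "BCI_correct", "BCI_error", "AE"}
_KNOWN_CONDITIONS = _ANTICIPATED | {"AO", "REST"}


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


@dataclass
class SpellerConfig:
    """Trial structure of the P300 feedback session."""

    n_fingers: int = 4
    reps_per_finger: int = 10
    flash_dur_s: float = 0.1
    isi_s: float = 0.2
    n_trials: int = 40
    n_forced_errors: int = 15
    anticipation_gap_s: float = 2.0  # last flash offset -> feedback onset
    feedback_flexion_s: float = 1.0
    feedback_extension_s: float = 1.0
    inter_trial_s: float = 3.0
    lead_in_s: float = 3.0

    def validate(self) -> None:
        _require(self.n_fingers >= 2, "SpellerConfig.n_fingers must be >= 2")
        _require(self.n_forced_errors <= self.n_trials,
                 "SpellerConfig.n_forced_errors must be <= n_trials")
        _require(self.anticipation_gap_s >= 0.7,
                 "SpellerConfig.anticipation_gap_s must cover the 0.7 s "
                 "pre-feedback analysis window")

    @property
    def flashes_per_trial(self) -> int:
        return self.n_fingers * self.reps_per_finger


@dataclass
class PassiveConfig:
    """Trial structure of the passive observation session."""

    n_actions: int = 60
    frac_anticipated: float = 0.5
    cue_lead_s: float = 1.0
    rest_range_s: tuple[float, float] = (2.5, 4.5)
    flexion_s: float = 1.0
    extension_s: float = 1.0
    lead_in_s: float = 3.0

    def validate(self) -> None:
        _require(0.0 <= self.frac_anticipated <= 1.0,
                 "PassiveConfig.frac_anticipated must be in [0, 1]")
        _require(self.rest_range_s[0] <= self.rest_range_s[1],
                 "PassiveConfig.rest_range_s must be ordered low <= high")
        _require(self.rest_range_s[0] >= self.cue_lead_s + 1.0,
                 "PassiveConfig rest must exceed cue lead + 1 s")


@dataclass
class ExecutionConfig:
    """Voluntary finger-movement block used for band calibration."""

    n_actions: int = 20
    rest_range_s: tuple[float, float] = (2.5, 4.5)
    flexion_s: float = 1.0
    extension_s: float = 1.0
    lead_in_s: float = 3.0

    def validate(self) -> None:
        _require(self.n_actions >= 1, "ExecutionConfig.n_actions must be >= 1")


@dataclass
class ArtifactConfig:
    """Optional EOG/EMG-like confound sources."""

    blink_rate_hz: float = 0.15
    blink_amp_uv: float = 60.0
    muscle_amp_uv: float = 8.0
    muscle_burst_rate_hz: float = 0.05
    enabled: bool = True


@dataclass
class EffectSpec:
    """Ground-truth effect magnitudes and bands.

    ERD depths are negative dB (power relative to rest), ERS positive dB.
    ``*_band`` fields are the analysis search ranges; ``*_source_band`` the
    subrange in which the generating oscillation actually lives.
    """

    mu_band: tuple[float, float] = (6.0, 15.0)
    beta_band: tuple[float, float] = (12.0, 30.0)
    ers_band: tuple[float, float] = (12.0, 17.0)
    mu_source_band: tuple[float, float] = (8.0, 13.0)
    beta_source_band: tuple[float, float] = (15.0, 25.0)
    anticipatory_erd_db: float = -3.0
    action_erd_db: float = -6.0
    ers_db: float = 3.0
    ers_window_s: tuple[float, float] = (0.8, 1.75)
    ne_amp_uv: float = -1.5
    ne_latency_s: float = 0.25
    pe_amp_uv: float = 8.0
    pe_latency_s: float = 0.50
    ip_amp_uv: float = -1.5
    ip_latency_s: float = 0.70
    p300_amp_uv: float = 5.0
    p300_latency_s: float = 0.35
    mu_amp_uv: float = 4.0
    beta_amp_uv: float = 2.5
    ers_amp_uv: float = 3.0
    alpha_amp_uv: float = 4.0
    noise_uv: float = 8.0
    shared_noise_uv: float = 4.0
    between_subject_sd: float = 0.2  # lognormal sigma on magnitudes

    def validate(self) -> None:
        _require(self.anticipatory_erd_db <= 0 and self.action_erd_db <= 0,
                 "EffectSpec ERD depths must be expressed as negative dB")
        _require(self.ers_db >= 0, "EffectSpec.ers_db must be non-negative dB")
        for name in ("mu_band", "beta_band", "ers_band",
                     "mu_source_band", "beta_source_band", "ers_window_s"):
            lo, hi = getattr(self, name)
            _require(lo < hi, f"EffectSpec.{name} must be ordered low < high")


@dataclass
class CohortSpec:
    """Full description of a simulated cohort."""

    n_subjects: int = 20
    seed: int = 0
    sfreq: float = 500.0
    speller: SpellerConfig = field(default_factory=SpellerConfig)
    passive: PassiveConfig = field(default_factory=PassiveConfig)
    execution: ExecutionConfig = field(default_factory=ExecutionConfig)
    effects: EffectSpec = field(default_factory=EffectSpec)
    artifacts: ArtifactConfig = field(default_factory=ArtifactConfig)

    def validate(self) -> None:
        _require(self.n_subjects >= 1, "CohortSpec.n_subjects must be >= 1")
        top = max(self.effects.beta_band[1], self.effects.beta_source_band[1])
        _require(self.sfreq > 2 * top,
                 "CohortSpec.sfreq must exceed twice the highest source band edge")
        self.speller.validate()
        self.passive.validate()
        self.execution.validate()
        self.effects.validate()


@dataclass
class SourceSpec:
    """One forward-mixed signal source.

    ``envelope_kind`` selects the time-course model: a constant-envelope
    narrowband oscillation, an ERD/ERS-modulated oscillation, a transient
    event-locked deflection, a flash-locked deflection, or pink noise.
    """

    center_channel: str
    spread: float = 0.5  # pattern width, radians of great-circle distance
    band: tuple[float, float] | None = None  # None = broadband
    envelope_kind: str = "constant"
    amplitude: float = 1.0  # uV rms (oscillatory) or uV peak (transient)
    lateralization: float = 1.0  # >1 down-weights the right hemisphere
    band_role: str | None = None  # mu | beta | ers for erd/ers envelopes
    latency_s: float = 0.0
    width_s: float = 0.2
    lock_kind: str = "feedback_onset"
    conditions: tuple[str, ...] | None = None  # None = all conditions
    targets_only: bool = False

    def validate(self) -> None:
        _require(self.spread > 0, "SourceSpec.spread must be positive")
        if self.envelope_kind not in ("transient_erp", "flash_erp"):
            # transient deflections may be negative-going (Ne, Ip)
            _require(self.amplitude >= 0, "SourceSpec.amplitude must be >= 0")
        if self.band is not None:
            _require(self.band[0] < self.band[1],
                     "SourceSpec.band must be ordered low < high")
        kinds = {"constant", "erd_profile", "ers_profile", "transient_erp",
                 "flash_erp", "pink_noise"}
        _require(self.envelope_kind in kinds,
                 f"SourceSpec.envelope_kind must be one of {sorted(kinds)}")


# ---------------------------------------------------------------------------
# envelopes


def erd_envelope(condition: str, times: np.ndarray, effects: EffectSpec,
                 band: str, flexion_s: float = 1.0,
                 extension_s: float = 1.0) -> np.ndarray:
    """Multiplicative amplitude envelope around a movement onset.

    ``times`` are seconds relative to movement (or feedback) onset.  The
    envelope equals 1 at rest.  Mu activity starts declining ~1 s before the
    onset whenever the action is anticipated (cued observation, BCI feedback,
    own execution) but not for unexpected observation; both rhythms reach
    their deepest suppression at the flexion apex and recover during
    extension.  On erroneous-feedback trials the low-beta envelope carries a
    synchronization bump inside the configured post-onset window.
    """
    if condition not in _KNOWN_CONDITIONS:
        raise ValueError(f"unknown condition label {condition!r}")
    if band not in ("mu", "beta", "ers"):
        raise ValueError(f"unknown band {band!r} (expected mu, beta or ers)")
    times = np.asarray(times, dtype=float)
    db = np.zeros_like(times)
    apex = flexion_s
    end = flexion_s + extension_s
    if condition == "REST":
        return np.ones_like(times)
    if band == "mu":
        if condition in _ANTICIPATED:
            knots_t = [-1.0, 0.0, apex, end]
            knots_db = [0.0, effects.anticipatory_erd_db,
                        effects.action_erd_db, 0.0]
        else:  # AO: no pre-onset decline
            knots_t = [0.0, apex, end]
            knots_db = [0.0, effects.action_erd_db, 0.0]
        db = np.interp(times, knots_t, knots_db, left=0.0, right=0.0)
    elif band == "beta":
        # beta declines only after the onset, in every active condition
        db = np.interp(times, [0.0, apex, end],
                       [0.0, effects.action_erd_db, 0.0], left=0.0, right=0.0)
    else:  # ers
        if condition == "BCI_error":
            lo, hi = effects.ers_window_s
            inside = (times >= lo) & (times <= hi)
            phase = (times[inside] - lo) / (hi - lo)
            db[inside] = effects.ers_db * np.sin(np.pi * phase) ** 2
    return 10.0 ** (db / 20.0)


def _hann_bump(width_s: float, sfreq: float) -> np.ndarray:
    n = max(int(round(width_s * sfreq)), 3)
    return np.hanning(n)


# ---------------------------------------------------------------------------
# forward model


def gaussian_pattern(montage: MontageLayout, center_channel: str,
                     spread: float, lateralization: float = 1.0) -> np.ndarray:
    """Isotropic Gaussian scalp pattern, peak 1 at the center channel."""
    if center_channel not in montage.channel_names:
        raise ValueError(f"source centered on unknown channel {center_channel!r}")
    d = montage.angular_distances(center_channel)
    w = np.exp(-(d ** 2) / (2.0 * spread ** 2))
    if lateralization != 1.0:
        right = montage.positions[:, 0] > 1e-9
        w = w.copy()
        w[right] /= lateralization
    return w


def pink_noise(n_samples: int, sfreq: float, rng: np.random.Generator,
               n_series: int = 1, f_lo: float = 0.3) -> np.ndarray:
    """1/f-power noise, unit variance in expectation, shape (n_series, n)."""
    freqs = np.fft.rfftfreq(n_samples, 1.0 / sfreq)
    amp = np.zeros_like(freqs, dtype=np.float32)
    nz = freqs >= f_lo
    amp[nz] = freqs[nz].astype(np.float32) ** np.float32(-0.5)
    # complex-normal spectrum == random phase with Rayleigh amplitude jitter
    spec = amp * (rng.standard_normal((n_series, len(freqs)), dtype=np.float32)
                  + 1j * rng.standard_normal((n_series, len(freqs)),
                                             dtype=np.float32))
    x = np.fft.irfft(spec, n=n_samples, axis=-1)
    # Parseval: normalize by the expected rather than realized variance
    norm = 2.0 * np.sqrt(np.sum(amp.astype(np.float64) ** 2)) / n_samples
    return x / np.float32(norm)


def _narrowband(n_samples: int, sfreq: float, band: tuple[float, float],
                rng: np.random.Generator) -> np.ndarray:
    """Unit-rms band-limited Gaussian noise carrier."""
    sos = sps.butter(4, band, btype="bandpass", fs=sfreq, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(n_samples))
    sd = x.std()
    return x / sd if sd > 0 else x


def _condition_envelope(schedule: EventSchedule, n_samples: int, sfreq: float,
                        effects: EffectSpec, band_role: str,
                        flexion_s: float, extension_s: float) -> np.ndarray:
    """Per-sample envelope from all movement/feedback onsets in a schedule."""
    env = np.ones(n_samples)
    onsets = schedule.events[
        schedule.events["kind"].isin(["movement_onset", "feedback_onset"])
    ]
    span_lo, span_hi = -1.5, flexion_s + extension_s + 0.5
    for onset, cond in zip(onsets["onset_s"], onsets["condition"]):
        i0 = max(int(np.floor((onset + span_lo) * sfreq)), 0)
        i1 = min(int(np.ceil((onset + span_hi) * sfreq)) + 1, n_samples)
        t_rel = np.arange(i0, i1) / sfreq - onset
        env[i0:i1] *= erd_envelope(cond, t_rel, effects, band_role,
                                   flexion_s, extension_s)
    return env


def synthesize_recording(schedule: EventSchedule, sources: list[SourceSpec],
                         montage: MontageLayout, seed: int | np.random.Generator,
                         sfreq: float = 500.0, duration: float | None = None,
                         effects: EffectSpec | None = None,
                         sensor_noise_uv: float = 0.0,
                         shared_noise_uv: float = 0.0,
                         flexion_s: float = 1.0,
                         extension_s: float = 1.0) -> RawRecording:
    """Linear forward mixing of envelope-modulated sources plus 1/f noise."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    effects = effects or EffectSpec()
    if duration is None:
        duration = schedule.end + 4.0
    n = int(round(duration * sfreq))
    patterns: list[np.ndarray] = []
    series: list[np.ndarray] = []

    for src in sources:
        src.validate()
        pattern = gaussian_pattern(montage, src.center_channel, src.spread,
                                   src.lateralization)
        ts = np.zeros(n)
        if src.envelope_kind == "pink_noise":
            ts = pink_noise(n, sfreq, rng)[0] * src.amplitude
        elif src.envelope_kind in ("constant", "erd_profile", "ers_profile"):
            if src.band is None:
                carrier = pink_noise(n, sfreq, rng)[0]
            else:
                carrier = _narrowband(n, sfreq, src.band, rng)
            env = np.ones(n)
            if src.envelope_kind != "constant":
                role = src.band_role or ("ers" if src.envelope_kind == "ers_profile" else "mu")
                env = _condition_envelope(schedule, n, sfreq, effects, role,
                                          flexion_s, extension_s)
            ts = carrier * env * src.amplitude
        elif src.envelope_kind in ("transient_erp", "flash_erp"):
            bump = _hann_bump(src.width_s, sfreq)
            half = len(bump) // 2
            if src.envelope_kind == "flash_erp":
                ev = schedule.of_kind("flash")
                if src.targets_only:
                    ev = ev[ev["is_target"].fillna(False).astype(bool)]
            else:
                ev = schedule.events[
                    schedule.events["kind"].isin(["movement_onset", "feedback_onset"])
                ]
                if src.conditions is not None:
                    ev = ev[ev["condition"].isin(src.conditions)]
            for onset in ev["onset_s"]:
                c = int(round((onset + src.latency_s) * sfreq))
                i0, i1 = c - half, c - half + len(bump)
                if i0 < 0 or i1 > n:
                    continue
                ts[i0:i1] += src.amplitude * bump
        patterns.append(pattern)
        series.append(ts)

    if shared_noise_uv > 0:
        # volume-conducted background common to all channels
        patterns.append(np.full(len(montage), shared_noise_uv))
        series.append(pink_noise(n, sfreq, rng)[0])

    # single sgemm: mixing all sources at once
    if patterns:
        P = np.asarray(np.stack(patterns, axis=1), dtype=np.float32)
        S = np.asarray(np.stack(series, axis=0), dtype=np.float32)
        data = P @ S
    else:
        data = np.zeros((len(montage), n), dtype=np.float32)
    if sensor_noise_uv > 0:
        data += np.float32(sensor_noise_uv) * pink_noise(
            n, sfreq, rng, n_series=len(montage))
    return RawRecording(data, sfreq, montage)


# ---------------------------------------------------------------------------
# schedules


def build_speller_schedule(cfg: SpellerConfig, rng: np.random.Generator) -> tuple[EventSchedule, dict]:
    """One P300 session: flash sequences, anticipation gap, feedback onsets.

    The attended (target) finger is assumed to be decoded correctly; forced
    errors are injected on a random subset of trials, exactly as the online
    loop did, which fixes every trial's feedback finger and condition label.
    """
    cfg.validate()
    soa = cfg.flash_dur_s + cfg.isi_s
    records = []
    t = cfg.lead_in_s
    targets = rng.integers(0, cfg.n_fingers, size=cfg.n_trials)
    forced = np.zeros(cfg.n_trials, dtype=bool)
    forced[rng.choice(cfg.n_trials, size=cfg.n_forced_errors, replace=False)] = True
    feedback = targets.copy()
    for i in np.flatnonzero(forced):
        others = [f for f in range(cfg.n_fingers) if f != targets[i]]
        feedback[i] = rng.choice(others)
    for trial in range(cfg.n_trials):
        cond = "BCI_error" if forced[trial] else "BCI_correct"
        order = np.concatenate([rng.permutation(cfg.n_fingers)
                                for _ in range(cfg.reps_per_finger)])
        for k, finger in enumerate(order):
            records.append(dict(onset_s=t + k * soa, kind="flash",
                                finger=int(finger),
                                is_target=bool(finger == targets[trial]),
                                condition=cond, trial_index=trial))
        t_fb = t + (len(order) - 1) * soa + cfg.flash_dur_s + cfg.anticipation_gap_s
        records.append(dict(onset_s=t_fb, kind="feedback_onset",
                            finger=int(feedback[trial]), is_target=None,
                            condition=cond, trial_index=trial))
        t = t_fb + cfg.feedback_flexion_s + cfg.feedback_extension_s + cfg.inter_trial_s
    truth = dict(targets=targets.tolist(), feedback=feedback.tolist(),
                 forced_error_trials=np.flatnonzero(forced).tolist())
    return EventSchedule.from_records(records), truth


def _observation_schedule(n_actions: int, labels: list[str],
                          rest_range_s: tuple[float, float],
                          flexion_s: float, extension_s: float,
                          lead_in_s: float, cue_lead_s: float,
                          rng: np.random.Generator) -> EventSchedule:
    records = []
    t = lead_in_s
    for trial, cond in enumerate(labels):
        t += rng.uniform(*rest_range_s)
        if cond == "AAO":
            records.append(dict(onset_s=t - cue_lead_s, kind="cue", finger=None,
                                is_target=None, condition=cond, trial_index=trial))
        records.append(dict(onset_s=t, kind="movement_onset", finger=None,
                            is_target=None, condition=cond, trial_index=trial))
        t += flexion_s + extension_s
        records.append(dict(onset_s=t + 0.5, kind="rest_onset", finger=None,
                            is_target=None, condition="REST", trial_index=trial))
    return EventSchedule.from_records(records)


def build_passive_schedule(cfg: PassiveConfig, rng: np.random.Generator) -> EventSchedule:
    """Passive session: balanced cued (AAO) / uncued (AO) assignment, shuffled."""
    cfg.validate()
    n_aao = int(round(cfg.n_actions * cfg.frac_anticipated))
    labels = ["AAO"] * n_aao + ["AO"] * (cfg.n_actions - n_aao)
    labels = list(np.array(labels)[rng.permutation(cfg.n_actions)])
    return _observation_schedule(cfg.n_actions, labels, cfg.rest_range_s,
                                 cfg.flexion_s, cfg.extension_s, cfg.lead_in_s,
                                 cfg.cue_lead_s, rng)


def build_execution_schedule(cfg: ExecutionConfig, rng: np.random.Generator) -> EventSchedule:
    cfg.validate()
    labels = ["AE"] * cfg.n_actions
    return _observation_schedule(cfg.n_actions, labels, cfg.rest_range_s,
                                 cfg.flexion_s, cfg.extension_s, cfg.lead_in_s,
                                 1.0, rng)


# ---------------------------------------------------------------------------
# cohort


def _subject_effects(effects: EffectSpec, rng: np.random.Generator) -> EffectSpec:
    """Per-subject draw: lognormal scatter on magnitudes, jittered mu band."""
    sd = effects.between_subject_sd
    out = EffectSpec(**asdict(effects))

    def scale() -> float:
        return float(rng.lognormal(mean=0.0, sigma=sd)) if sd > 0 else 1.0

    out.anticipatory_erd_db = effects.anticipatory_erd_db * scale()
    out.action_erd_db = effects.action_erd_db * scale()
    out.ers_db = effects.ers_db * scale()
    out.ne_amp_uv = effects.ne_amp_uv * scale()
    out.pe_amp_uv = effects.pe_amp_uv * scale()
    out.ip_amp_uv = effects.ip_amp_uv * scale()
    out.p300_amp_uv = effects.p300_amp_uv * scale()
    lo, hi = effects.mu_source_band
    center = rng.uniform((lo + hi) / 2 - 1.0, (lo + hi) / 2 + 1.0)
    half = (hi - lo) / 2
    out.mu_source_band = (max(center - half, effects.mu_band[0]),
                          min(center + half, effects.mu_band[1]))
    return out


def default_sources(eff: EffectSpec, task: str) -> list[SourceSpec]:
    """The study's assumed source set for one session of one subject."""
    lat = 2.0  # contralateral (left hemisphere) predominance, right-hand task
    sources = [
        SourceSpec("C3", spread=0.5, band=eff.mu_source_band,
                   envelope_kind="erd_profile", amplitude=eff.mu_amp_uv,
                   lateralization=lat, band_role="mu"),
        SourceSpec("C1", spread=0.5, band=eff.beta_source_band,
                   envelope_kind="erd_profile", amplitude=eff.beta_amp_uv,
                   lateralization=lat, band_role="beta"),
        SourceSpec("Oz", spread=0.4, band=(8.0, 12.0),
                   envelope_kind="constant", amplitude=eff.alpha_amp_uv),
    ]
    if task == "bci":
        sources.append(
            SourceSpec("C1", spread=0.5, band=eff.ers_band,
                       envelope_kind="ers_profile", amplitude=eff.ers_amp_uv,
                       lateralization=lat, band_role="ers"))
        for name, amp, lat_s, width in (
                ("ne", eff.ne_amp_uv, eff.ne_latency_s, 0.15),
                ("pe", eff.pe_amp_uv, eff.pe_latency_s, 0.20),
                ("ip", eff.ip_amp_uv, eff.ip_latency_s, 0.15)):
            sources.append(
                SourceSpec("FCz", spread=0.5, band=None,
                           envelope_kind="transient_erp", amplitude=amp,
                           latency_s=lat_s, width_s=width,
                           conditions=("BCI_error",)))
        sources.append(
            SourceSpec("Pz", spread=0.6, band=None, envelope_kind="flash_erp",
                       amplitude=eff.p300_amp_uv, latency_s=eff.p300_latency_s,
                       width_s=0.30, targets_only=True))
    return sources


def _add_artifacts(data: np.ndarray, montage: MontageLayout, sfreq: float,
                   cfg: ArtifactConfig, rng: np.random.Generator) -> None:
    """Blink train at the frontopolar sites, EMG bursts at the temporal sites."""
    if not cfg.enabled:
        return
    n = data.shape[1]
    dur = n / sfreq
    # blinks: ~300 ms positive frontopolar deflections at Poisson times
    pat = 0.5 * (gaussian_pattern(montage, "Fp1", 0.45)
                 + gaussian_pattern(montage, "Fp2", 0.45))
    n_blinks = rng.poisson(cfg.blink_rate_hz * dur)
    bump = np.hanning(int(0.3 * sfreq))
    ts = np.zeros(n)
    for t0 in rng.uniform(0, dur, size=n_blinks):
        i0 = int(t0 * sfreq)
        i1 = min(i0 + len(bump), n)
        ts[i0:i1] += cfg.blink_amp_uv * bump[: i1 - i0]
    data += pat[:, None] * ts[None, :]
    # muscle: 25-40 Hz bursts (~1 s) at T7 and T8 independently; the carrier
    # is only synthesized inside each burst window
    sos = sps.butter(4, (25.0, 40.0), btype="bandpass", fs=sfreq, output="sos")
    burst = np.hanning(int(1.0 * sfreq))
    for site in ("T7", "T8"):
        patm = gaussian_pattern(montage, site, 0.3)
        n_bursts = rng.poisson(cfg.muscle_burst_rate_hz * dur)
        ts = np.zeros(n)
        for t0 in rng.uniform(0, dur, size=n_bursts):
            i0 = int(t0 * sfreq)
            i1 = min(i0 + len(burst), n)
            seg = sps.sosfiltfilt(sos, rng.standard_normal(i1 - i0 + 400))[200:200 + i1 - i0]
            sd = seg.std()
            if sd > 0:
                seg = seg / sd
            ts[i0:i1] += cfg.muscle_amp_uv * burst[: i1 - i0] * seg
        data += patm[:, None] * ts[None, :]


@dataclass
class SubjectData:
    """All sessions of one simulated subject plus the ground-truth sidecar."""

    subject_id: str
    recordings: dict[str, RawRecording]
    schedules: dict[str, EventSchedule]
    ground_truth: dict


def simulate_subject(spec: CohortSpec, subject_index: int,
                     rng: np.random.Generator) -> SubjectData:
    montage = standard_montage()
    eff = _subject_effects(spec.effects, rng)
    recordings: dict[str, RawRecording] = {}
    schedules: dict[str, EventSchedule] = {}

    sched_bci, bci_truth = build_speller_schedule(spec.speller, rng)
    sched_pas = build_passive_schedule(spec.passive, rng)
    sched_exe = build_execution_schedule(spec.execution, rng)
    session_cfg = {
        "execution": (sched_exe, "execution", spec.execution.flexion_s,
                      spec.execution.extension_s),
        "passive": (sched_pas, "passive", spec.passive.flexion_s,
                    spec.passive.extension_s),
        "bci": (sched_bci, "bci", spec.speller.feedback_flexion_s,
                spec.speller.feedback_extension_s),
    }
    for name, (sched, task, flex, ext) in session_cfg.items():
        raw = synthesize_recording(
            sched, default_sources(eff, task),
            montage, rng, sfreq=spec.sfreq, effects=eff,
            sensor_noise_uv=eff.noise_uv, shared_noise_uv=eff.shared_noise_uv,
            flexion_s=flex, extension_s=ext)
        _add_artifacts(raw.data, montage, spec.sfreq, spec.artifacts, rng)
        recordings[name] = raw
        schedules[name] = sched

    truth = dict(
        subject_index=subject_index,
        effects=asdict(eff),
        bci=bci_truth,
    )
    return SubjectData(f"sub-{subject_index:02d}", recordings, schedules, truth)


def simulate_cohort(spec: CohortSpec) -> list[SubjectData]:
    """Deterministic cohort simulation: one independent RNG stream per subject."""
    spec.validate()
    ss = np.random.SeedSequence(spec.seed)
    children = ss.spawn(spec.n_subjects)
    return [simulate_subject(spec, i, np.random.default_rng(children[i]))
            for i in range(spec.n_subjects)]


def ground_truth_json(sub: SubjectData) -> str:
    return json.dumps(sub.ground_truth, indent=1)
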