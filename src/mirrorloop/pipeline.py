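"""End-to-end orchestration: simulate -> preprocess -> CSP -> ERD/S -> stats.

The six group-level contrasts cover every comparison the analysis plan
defines: cued-observation anticipatory mu ERD against zero, cued vs uncued
observation mu ERD, pre-feedback mu ERD against zero, correct-vs-error
feedback ERD (mu and beta; expected null), correct-vs-error low-beta ERS,
and the spatio-temporal error-potential contrast on feedback-locked ERPs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import bci as bci_mod
from . import erp as erp_mod
from .csp import CSP, BandSpec, bandpass_epochs, select_subject_band
from .montage import standard_montage
from .preprocess import baseline_correct, extract_epochs, reject_epochs
from .simulate import CohortSpec, SubjectData
from .stats import (TFCEParams, channel_adjacency, cohens_d_cluster,
                    permutation_test_1d, spatiotemporal_cluster_test)
from .tfr import DEFAULT_FREQS, erds_db, tfr_transform

logger = logging.getLogger(__name__)

CONTRAST_NAMES = (
    "aao_anticipation_mu_vs_zero",
    "aao_vs_ao_mu",
    "bci_prefeedback_mu_vs_zero",
    "bci_correct_vs_error_erd",
    "bci_error_vs_correct_ers",
    "errp_spatiotemporal",
)


@dataclass
class StatsParams:
    alpha: float = 0.05
    n_perm: int = 10000
    tfce: TFCEParams = field(default_factory=TFCEParams)
    erp_threshold: float = 20.0


@dataclass
class PipelineConfig:
    cohort: CohortSpec = field(default_factory=CohortSpec)
    seed: int = 0
    # preprocessing
    band: tuple[float, float] = (1.0, 40.0)
    # the simulated amplifier applies the mains notch at acquisition time, so
    # the offline default leaves it off
    line_freq: float | None = None
    run_ica: bool = True
    ica_components: int = 14
    ica_decim: int = 10
    reject_uv: float = 120.0
    # CSP
    csp_components: int = 6
    min_central_frac: float = 0.6
    # TFR / ERDS
    fwhm_t: float = 0.14
    erds_decim: int = 10  # time-course decimation before 1-D statistics
    # statistics
    stats: StatsParams = field(default_factory=StatsParams)
    out_dir: str | None = None

    def validate(self) -> None:
        if not 0 < self.stats.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        self.cohort.validate()


@dataclass
class ContrastSummary:
    name: str
    significant: bool
    clusters: list  # dicts: time range / channels / stat / p
    extra: dict = field(default_factory=dict)


@dataclass
class RunReport:
    contrasts: dict[str, ContrastSummary]
    session_accuracies: list[float]
    decoding_accuracies: list[float]
    subject_bands: list[dict]
    recovery: list[dict]
    config_fingerprint: dict
    timings: dict[str, float]

    def to_json(self) -> str:
        def default(o):
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return dataclasses.asdict(o)
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, slice):
                return [o.start, o.stop]
            raise TypeError(type(o))

        return json.dumps(asdict(self), default=default, indent=1)


# ---------------------------------------------------------------------------
# per-subject analysis


def _erds_courses(raw, schedule, filters_band: BandSpec, model: CSP,
                  lock: str, condition_sets: dict[str, list[str] | None],
                  rest_lock: str, rest_window: tuple[float, float],
                  fwhm_t: float, tmin: float = -1.5, tmax: float = 2.0):
    """Band ERD/S time-courses on CSP components, one per condition set.

    The TFR of the full active epoch set and of the rest epochs is computed
    once; condition subsets reuse it.  Power is *induced* power: the
    per-condition evoked response is subtracted from each epoch first (with
    the sqrt(n/(n-1)) variance restoration), so phase-locked transients such
    as the error potentials cannot leak into the band-power contrasts.
    """
    active = extract_epochs(raw, schedule, lock, tmin, tmax)
    rest = extract_epochs(raw, schedule, rest_lock, *rest_window)
    comp_active = model.transform_epochs(active)
    comp_rest = model.transform_epochs(rest)

    def subtract_evoked(data: np.ndarray, groups: np.ndarray) -> None:
        for g in np.unique(groups):
            idx = np.flatnonzero(groups == g)
            n = len(idx)
            if n < 2:
                continue
            evoked = data[idx].mean(axis=0)
            data[idx] = (data[idx] - evoked) * np.sqrt(n / (n - 1))

    subtract_evoked(comp_active.data,
                    active.metadata["condition"].to_numpy())
    subtract_evoked(comp_rest.data, np.zeros(len(comp_rest)))
    lo, hi = filters_band.range_hz
    fsel = DEFAULT_FREQS[(DEFAULT_FREQS >= lo - 1e-9) & (DEFAULT_FREQS <= hi + 1e-9)]
    tfr_a = tfr_transform(comp_active, freqs=fsel, fwhm_t=fwhm_t,
                          dtype=np.complex64)
    tfr_r = tfr_transform(comp_rest, freqs=fsel, fwhm_t=fwhm_t,
                          dtype=np.complex64)
    conds = active.metadata["condition"].to_numpy()
    out = {}
    for key, wanted in condition_sets.items():
        if wanted is None:
            sub = tfr_a
        else:
            mask = np.isin(conds, wanted)
            sub = dataclasses.replace(tfr_a, power=tfr_a.power[mask])
        out[key] = erds_db(sub, tfr_r, filters_band)
    return out


@dataclass
class SubjectAnalysis:
    bands: dict[str, BandSpec]
    erds: dict[str, np.ndarray]  # contrast input name -> time-course (dB)
    erds_times: np.ndarray
    evoked_error: np.ndarray
    evoked_correct: np.ndarray
    evoked_times: np.ndarray
    ch_names: tuple[str, ...]
    session_accuracy: float
    decoding_accuracy: float


def analyze_subject(sub: SubjectData, cfg: PipelineConfig) -> SubjectAnalysis:
    montage = standard_montage()
    eff = cfg.cohort.effects
    # band-pass (and optional notch) per session; one ICA decomposition per
    # subject, fitted on the longest session and applied to all of them
    from .preprocess import (FilterSpec, bandpass, classify_components,
                             fit_ica, notch, remove_components,
                             rereference_average)

    filtered = {}
    for session, raw in sub.recordings.items():
        out = bandpass(raw, FilterSpec(band=cfg.band))
        if cfg.line_freq is not None:
            out = notch(out, cfg.line_freq)
        filtered[session] = out
    clean = {}
    if cfg.run_ica:
        longest = max(filtered, key=lambda s: filtered[s].n_samples)
        ica = fit_ica(filtered[longest], n_components=cfg.ica_components,
                      seed=cfg.seed, decim=cfg.ica_decim, max_iter=200,
                      tol=2e-3)
        labels = classify_components(ica, filtered[longest])
        drop = [lb for lb in ("eog", "muscle") if lb in labels]
        for session, raw in filtered.items():
            cleaned = remove_components(raw, ica, drop) if drop else raw
            clean[session] = rereference_average(cleaned)
    else:
        clean = {s: rereference_average(r) for s, r in filtered.items()}

    # --- subject-specific bands from the voluntary-movement block (C3)
    exe_raw, exe_sched = clean["execution"], sub.schedules["execution"]
    c3 = montage.index("C3")
    exe_ep = extract_epochs(exe_raw, exe_sched, "movement_onset", -1.0, 2.5)
    exe_rest = extract_epochs(exe_raw, exe_sched, "rest_onset", 0.0, 2.0)
    tfr_a = tfr_transform(exe_ep.data[:, [c3]], exe_ep.sfreq, exe_ep.times,
                          fwhm_t=cfg.fwhm_t, dtype=np.complex64)
    tfr_r = tfr_transform(exe_rest.data[:, [c3]], exe_rest.sfreq,
                          exe_rest.times, fwhm_t=cfg.fwhm_t,
                          dtype=np.complex64)
    from .tfr import rest_reference

    ref = rest_reference(tfr_r)[0]  # (freqs,)
    db_map = 10 * np.log10(
        np.median(tfr_a.power[:, 0], axis=0) / ref[:, None])
    bands = {
        "mu": select_subject_band(db_map, DEFAULT_FREQS, exe_ep.times,
                                  eff.mu_band, "mu"),
        "beta": select_subject_band(db_map, DEFAULT_FREQS, exe_ep.times,
                                    eff.beta_band, "beta"),
        "ers": BandSpec("ers", eff.ers_band),
    }

    # --- CSP per band and session, then band ERD/S time-courses
    def fit_band_csp(raw, sched, band: BandSpec, active_lock: str,
                     active_window: tuple[float, float],
                     rest_lock: str, rest_window: tuple[float, float],
                     active_conditions: list[str] | None = None,
                     tail: str = "both") -> CSP:
        filt = bandpass_epochs(
            extract_epochs(raw, sched, active_lock, *active_window,
                           conditions=active_conditions), band.range_hz)
        rest = bandpass_epochs(
            extract_epochs(raw, sched, rest_lock, *rest_window), band.range_hz)
        model = CSP(n_components=cfg.csp_components).fit_epochs(
            filt.data, rest.data)
        if tail == "top":
            # synchronization sources raise active-class variance: keep only
            # the high-eigenvalue tail as candidates
            model.candidates_ = [i for i in model.candidates_
                                 if i < cfg.csp_components // 2]
            model.selected_ = list(model.candidates_)
        try:
            model.select_central(montage, cfg.min_central_frac)
        except ValueError:
            # fall back to the single most central candidate
            frac = model.central_fractions(montage)
            best = max(model.candidates_, key=lambda i: frac[i])
            logger.warning("no component passed the central criterion; "
                           "keeping the most central candidate")
            model.selected_ = [best]
        return model

    erds: dict[str, np.ndarray] = {}
    times_out = None
    pas_raw, pas_sched = clean["passive"], sub.schedules["passive"]
    bci_raw, bci_sched = clean["bci"], sub.schedules["bci"]
    d = cfg.erds_decim

    for band_name in ("mu", "beta"):
        band = bands[band_name]
        csp_pas = fit_band_csp(pas_raw, pas_sched, band, "movement_onset",
                               (0.0, 2.0), "rest_onset", (0.0, 2.0))
        courses = _erds_courses(
            pas_raw, pas_sched, band, csp_pas, "movement_onset",
            {"AAO": ["AAO"], "AO": ["AO"]}, "rest_onset", (0.0, 2.0),
            cfg.fwhm_t)
        for key, tc in courses.items():
            erds[f"passive_{key}_{band_name}"] = tc.values[::d]
            times_out = tc.times[::d]
        csp_bci = fit_band_csp(bci_raw, bci_sched, band, "feedback_onset",
                               (0.0, 2.0), "feedback_onset", (-4.0, -2.0))
        courses = _erds_courses(
            bci_raw, bci_sched, band, csp_bci, "feedback_onset",
            {"correct": ["BCI_correct"], "error": ["BCI_error"], "all": None},
            "feedback_onset", (-4.0, -2.0), cfg.fwhm_t)
        for key, tc in courses.items():
            erds[f"bci_{key}_{band_name}"] = tc.values[::d]
    band = bands["ers"]
    # the ERS generator raises variance inside the post-error window, so the
    # active class is the error-trial ERS window and only the top tail of the
    # eigenvalue spectrum is a synchronization candidate
    csp_ers = fit_band_csp(bci_raw, bci_sched, band, "feedback_onset",
                           (0.75, 1.8), "feedback_onset", (-4.0, -2.0),
                           active_conditions=["BCI_error"], tail="top")
    courses = _erds_courses(
        bci_raw, bci_sched, band, csp_ers, "feedback_onset",
        {"correct": ["BCI_correct"], "error": ["BCI_error"]},
        "feedback_onset", (-4.0, -2.0), cfg.fwhm_t)
    for key, tc in courses.items():
        erds[f"bci_{key}_ers"] = tc.values[::d]

    # --- feedback-locked ERPs
    ep = extract_epochs(bci_raw, bci_sched, "feedback_onset", -1.0, 1.0)
    ep = baseline_correct(ep, (-1.0, -0.2))
    ep = reject_epochs(ep, cfg.reject_uv)
    evoked = erp_mod.average_evoked(ep, "condition", lock_kind="feedback_onset")

    # --- P300 decoding and accuracy bookkeeping (flash responses are slow
    # potentials; narrow the passband before feature extraction)
    from .preprocess import FilterSpec as _FS
    from .preprocess import bandpass as _bp

    flash_raw = _bp(bci_raw, _FS(band=(0.5, 12.0)))
    flash_ep = extract_epochs(flash_raw, bci_sched, "flash", 0.0, 0.8)
    feats = bci_mod.extract_flash_features(flash_ep)
    n_fingers = cfg.cohort.speller.n_fingers
    decisions = bci_mod.decode_session(feats, n_fingers)
    targets = np.asarray(sub.ground_truth["bci"]["targets"])
    decoding_acc = float((decisions == targets).mean())
    fb = bci_sched.of_kind("feedback_onset")
    session_acc = float((fb["finger"].to_numpy(dtype=int) == targets).mean())

    return SubjectAnalysis(bands, erds, times_out,
                           evoked.averages["BCI_error"],
                           evoked.averages["BCI_correct"], evoked.times,
                           evoked.ch_names, session_acc, decoding_acc)


# ---------------------------------------------------------------------------
# group level


def _stack(analyses: list[SubjectAnalysis], key: str) -> np.ndarray:
    return np.stack([a.erds[key] for a in analyses])


def _window(times: np.ndarray, lo: float, hi: float) -> np.ndarray:
    return (times >= lo - 1e-9) & (times <= hi + 1e-9)


def _summarize_1d(name: str, res, times: np.ndarray) -> ContrastSummary:
    clusters = []
    for sl, stat, p in zip(res.clusters, res.cluster_stats, res.p_values):
        idx = np.arange(sl.start, sl.stop)
        clusters.append(dict(time_range=[float(times[idx[0]]),
                                         float(times[idx[-1]])],
                             mean_F=float(res.stat_map[idx].mean()),
                             enhanced_max=float(stat), p=float(p)))
    return ContrastSummary(name, res.any_significant, clusters)


def run_all(config: PipelineConfig) -> RunReport:
    """Execute the full analysis graph on a freshly simulated cohort."""
    config.validate()
    config.cohort.seed = config.seed
    timings: dict[str, float] = {}
    t0 = time.perf_counter()
    # subjects are simulated and analyzed one at a time; raw recordings are
    # released as soon as the per-subject derivatives exist
    from .simulate import simulate_subject

    ss = np.random.SeedSequence(config.cohort.seed)
    children = ss.spawn(config.cohort.n_subjects)
    analyses: list[SubjectAnalysis] = []
    for i in range(config.cohort.n_subjects):
        sub = simulate_subject(config.cohort, i, np.random.default_rng(children[i]))
        analyses.append(analyze_subject(sub, config))
        del sub
    timings["subjects"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    times = analyses[0].erds_times
    sp = config.stats
    contrasts: dict[str, ContrastSummary] = {}

    def run_1d(name: str, a: np.ndarray, b: np.ndarray | None,
               window: tuple[float, float], seed_offset: int) -> ContrastSummary:
        m = _window(times, *window)
        res = permutation_test_1d(a[:, m], None if b is None else b[:, m],
                                  sp.tfce, sp.n_perm,
                                  seed=config.seed + seed_offset,
                                  alpha=sp.alpha)
        return _summarize_1d(name, res, times[m])

    contrasts["aao_anticipation_mu_vs_zero"] = run_1d(
        "aao_anticipation_mu_vs_zero", _stack(analyses, "passive_AAO_mu"),
        None, (-1.0, 0.25), 1)
    contrasts["aao_vs_ao_mu"] = run_1d(
        "aao_vs_ao_mu", _stack(analyses, "passive_AAO_mu"),
        _stack(analyses, "passive_AO_mu"), (-1.0, 0.5), 2)
    contrasts["bci_prefeedback_mu_vs_zero"] = run_1d(
        "bci_prefeedback_mu_vs_zero", _stack(analyses, "bci_all_mu"),
        None, (-1.0, 0.0), 3)
    erd_sub = {}
    for band_name in ("mu", "beta"):
        erd_sub[band_name] = run_1d(
            f"bci_correct_vs_error_erd_{band_name}",
            _stack(analyses, f"bci_error_{band_name}"),
            _stack(analyses, f"bci_correct_{band_name}"), (0.0, 2.0),
            4 if band_name == "mu" else 5)
    contrasts["bci_correct_vs_error_erd"] = ContrastSummary(
        "bci_correct_vs_error_erd",
        erd_sub["mu"].significant or erd_sub["beta"].significant,
        erd_sub["mu"].clusters + erd_sub["beta"].clusters,
        extra={"mu": asdict(erd_sub["mu"]), "beta": asdict(erd_sub["beta"])})
    contrasts["bci_error_vs_correct_ers"] = run_1d(
        "bci_error_vs_correct_ers", _stack(analyses, "bci_error_ers"),
        _stack(analyses, "bci_correct_ers"), (0.0, 2.0), 6)

    # spatio-temporal ErrP contrast
    montage = standard_montage()
    adj = channel_adjacency(montage)
    err = np.stack([a.evoked_error for a in analyses])
    cor = np.stack([a.evoked_correct for a in analyses])
    etimes = analyses[0].evoked_times
    m = _window(etimes, -0.2, 1.0)
    res = spatiotemporal_cluster_test(err[:, :, m], cor[:, :, m],
                                      threshold=sp.erp_threshold,
                                      adjacency=adj, n_perm=sp.n_perm,
                                      seed=config.seed + 7, alpha=sp.alpha)
    clusters = []
    for (ch_i, t_i), mass, p in zip(res.clusters, res.cluster_stats, res.p_values):
        d = cohens_d_cluster(err[:, :, m], cor[:, :, m], (ch_i, t_i))
        clusters.append(dict(
            channels=sorted({montage.channel_names[c] for c in ch_i}),
            time_range=[float(etimes[m][t_i.min()]), float(etimes[m][t_i.max()])],
            mean_F=float(res.stat_map[ch_i, t_i].mean()),
            mass=float(mass), p=float(p), cohens_d=float(d)))
    contrasts["errp_spatiotemporal"] = ContrastSummary(
        "errp_spatiotemporal", res.any_significant, clusters)
    timings["stats"] = time.perf_counter() - t0

    recovery = recovery_table(contrasts, analyses, config)
    report = RunReport(
        contrasts=contrasts,
        session_accuracies=[a.session_accuracy for a in analyses],
        decoding_accuracies=[a.decoding_accuracy for a in analyses],
        subject_bands=[{k: list(v.range_hz) for k, v in a.bands.items()}
                       for a in analyses],
        recovery=recovery,
        config_fingerprint={"seed": config.seed,
                            "n_subjects": config.cohort.n_subjects,
                            "n_perm": sp.n_perm, "alpha": sp.alpha},
        timings=timings,
    )
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(report.to_json())
        # persist the group-level ERD/S time-courses in long format
        from .h5io import erds_to_tsv

        rows = []
        for i, a in enumerate(analyses):
            for key, values in a.erds.items():
                band_name = key.rsplit("_", 1)[1]
                rows.append(dict(subject=f"sub-{i:02d}", condition=key,
                                 band=band_name, times=a.erds_times,
                                 values=values))
        erds_to_tsv(out / "erds_timecourses.tsv", rows)
    return report


def _overlap_frac(found: tuple[float, float], gen: tuple[float, float]) -> float:
    """Fraction of the found cluster lying inside the generating window."""
    lo = max(found[0], gen[0])
    hi = min(found[1], gen[1])
    width = found[1] - found[0]
    if width <= 0:  # single-sample cluster: inside or not
        return 1.0 if gen[0] <= found[0] <= gen[1] else 0.0
    return max(0.0, hi - lo) / width


def recovery_table(contrasts: dict[str, ContrastSummary],
                   analyses: list[SubjectAnalysis],
                   config: PipelineConfig) -> list[dict]:
    """Configured vs recovered effect magnitudes with detection flags.

    Detection requires a significant cluster whose time extent overlaps the
    generating window by at least 50%.
    """
    eff = config.cohort.effects
    times = analyses[0].erds_times
    rows = []

    def detected(summary: ContrastSummary, window: tuple[float, float]) -> bool:
        return any(c["p"] < config.stats.alpha
                   and _overlap_frac(tuple(c["time_range"]), window) >= 0.5
                   for c in summary.clusters)

    # anticipatory mu ERD: mean pre-onset dB over [-0.5, 0]
    pre = _window(times, -0.5, 0.0)
    rec = float(np.mean([a.erds["bci_all_mu"][pre].mean() for a in analyses]))
    rows.append(dict(effect="anticipatory_mu_erd_db",
                     configured=eff.anticipatory_erd_db, recovered=rec,
                     detected=detected(contrasts["bci_prefeedback_mu_vs_zero"],
                                       (-1.0, 0.0))))
    # action mu ERD: minimum of the time-course
    rec = float(np.mean([a.erds["bci_all_mu"].min() for a in analyses]))
    rows.append(dict(effect="action_mu_erd_db", configured=eff.action_erd_db,
                     recovered=rec, detected=None))
    # error ERS: peak of the error-correct ers difference
    diff = np.mean([a.erds["bci_error_ers"] - a.erds["bci_correct_ers"]
                    for a in analyses], axis=0)
    rows.append(dict(effect="error_ers_db", configured=eff.ers_db,
                     recovered=float(diff.max()),
                     detected=detected(contrasts["bci_error_vs_correct_ers"],
                                       eff.ers_window_s)))
    # Pe difference at the fronto-central set
    montage = standard_montage()
    picks = [montage.index(c) for c in erp_mod.FRONTOCENTRAL]
    etimes = analyses[0].evoked_times
    w = _window(etimes, *erp_mod.DEFAULT_WINDOWS["oPe"])
    pe = float(np.mean([(a.evoked_error - a.evoked_correct)[picks][:, w].mean()
                        for a in analyses]))
    pe_win = (eff.pe_latency_s - 0.1, eff.pe_latency_s + 0.1)
    rows.append(dict(effect="pe_difference_uv", configured=eff.pe_amp_uv,
                     recovered=pe,
                     detected=detected(contrasts["errp_spatiotemporal"], pe_win)))
    # null check: mu/beta ERD difference between correct and error
    rows.append(dict(effect="correct_vs_error_erd_difference", configured=0.0,
                     recovered=None,
                     detected=contrasts["bci_correct_vs_error_erd"].significant))
    return rows
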