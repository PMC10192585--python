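# mirrorloop

Simulation and analysis of sensorimotor EEG during action observation inside
a P300 brain–computer-interface loop.

When people watch a movement — their own, someone else's, or a virtual
hand's — the sensorimotor mu (~6–15 Hz) and beta (~12–30 Hz) rhythms over
central scalp desynchronize, and when the observed action *contradicts*
their intention, the EEG adds a fronto-central error-related potential
(Ne/Pe/Ip complex) and a transient low-beta (12–17 Hz) synchronization.
`mirrorloop` is a complete, seeded re-implementation of the analysis chain
used to measure these signatures, together with a synthetic-cohort
generator that produces multichannel recordings with *known* effect sizes,
so every stage can be validated against ground truth:

* **Generator** — 48-channel 10-10 montage at 500 Hz; P300-speller sessions
  (40 trials × 40 flashes, 15 deliberately falsified feedbacks → maximum
  accuracy 62.5%), passive observation sessions (60 actions, half cued 1 s
  ahead), linear forward mixing of envelope-modulated narrowband sources,
  ERP transients, 1/f background, ocular/muscular artifact sources. Output:
  EDF + events TSV + ground-truth JSON.
* **Preprocessing** — zero-phase Butterworth 1–40 Hz, seeded FastICA with
  heuristic ocular/muscular component labelling, average reference,
  epoching, baseline correction, amplitude-based epoch rejection.
* **CSP** — two-class common spatial patterns (active observation vs rest)
  with covariance cleaning, shrinkage, and selection of sensorimotor
  (central) patterns, solving `C_a w = λ (C_a + C_r) w`.
* **Time–frequency** — complex Morlet transform with 140 ms
  amplitude-envelope FWHM (spectral FWHM ≈ 4.5 Hz); ERD/S in dB relative to
  the median resting power, `10·log10(P_active / median P_rest)`.
* **Statistics** — one-sample/paired F = t² time-courses, threshold-free
  cluster enhancement (E = 0.5, H = 2), sign-flip permutation nulls (exact
  enumeration on small designs), spatio-temporal cluster-mass tests with
  montage adjacency, per-cluster Cohen's d.
* **Speller decoding** — windowed/decimated flash features, shrinkage LDA,
  per-trial finger selection, forced-error accounting.

## Worked example

```python
from mirrorloop import CohortSpec, PipelineConfig, run_all

cfg = PipelineConfig(cohort=CohortSpec(n_subjects=20), seed=1)
cfg.stats.n_perm = 1000
report = run_all(cfg)

for name, c in report.contrasts.items():
    print(f"{name:32s} significant={c.significant}")
print("feedback accuracy:", set(report.session_accuracies))
print("offline decoding :", round(sum(report.decoding_accuracies) / 20, 3))
```

prints (seed 1):

```
aao_anticipation_mu_vs_zero      significant=True
aao_vs_ao_mu                     significant=True
bci_prefeedback_mu_vs_zero       significant=True
bci_correct_vs_error_erd         significant=False
bci_error_vs_correct_ers         significant=True
errp_spatiotemporal              significant=True
feedback accuracy: {0.625}
offline decoding : 0.961
```

Reading: the cued-observation and pre-feedback mu desynchronizations are
detected against zero (clusters beginning ~0.8 s before movement onset), the
error-vs-correct low-beta synchronization forms a cluster inside its
generating 0.8–1.75 s window, the fronto-central Pe cluster lands at
~0.45–0.55 s — while the mu/beta ERD contrast between correct and erroneous
feedback, for which no effect is generated, stays null. Feedback accuracy is
pinned at exactly 62.5% by the 15 forced errors; the offline cross-validated
decoder recovers the attended finger on ~96% of trials.
`report.recovery` compares configured vs recovered effect magnitudes
(e.g. ERS configured +3.0 dB, recovered ≈ +3.1 dB on this run).

A command-line interface wraps the same calls:

```
mirrorloop simulate --config cohort.yaml --out data/ --seed 1
mirrorloop run-all  --config pipeline.yaml --out results/ --seed 1
```

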