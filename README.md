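# tgcwm

Theta-gamma coupling and band-power analysis of visual working-memory EEG,
with a synthetic-data generator for end-to-end validation.

## The problem

In visuospatial working-memory (VWM) experiments, the phase of frontal
theta oscillations (4–8 Hz) organizes the amplitude of posterior gamma
oscillations (30–80 Hz). Clinical EEG studies of this theta-gamma coupling
(TGC) — for instance in mild cognitive impairment, before and after
repetitive transcranial magnetic stimulation (rTMS) — combine several
standard stages: artifact cleaning, epoching around task events, band power
per scalp region and task phase, cross-frequency coupling estimation, and
behavioral capacity measures, followed by group statistics with FDR
control. `tgcwm` implements that full pipeline as a tested library and CLI.

Because subject-level EEG from such studies is rarely deposited, the
package ships a first-class synthetic-data module that generates recordings
with *known* coupling, noise and artifact structure, so every downstream
stage can be validated against ground truth.

## The measures

**Modulation index (MI).** Theta phase φ(t) and gamma amplitude A(t) come
from the Hilbert transform of the band-passed signal. Phase is divided into
N = 18 bins of 20°; the normalized mean amplitude per bin P_i gives

    MI = (1 / log N) · Σᵢ P_i · log(P_i / (1/N)),

the KL divergence of P from the uniform distribution, normalized to [0, 1]:
0 means no phase-amplitude coupling, 1 means all amplitude in one phase bin.

**Phase-phase coupling (PPC).** The n:m phase-locking value
|⟨exp(i(n·φ_γ − m·φ_θ))⟩| (default 1:6).

**Band power.** One-sided FFT power on 2-s analysis windows (0.5 Hz grid),
summed over half-open bands delta 0.5–4, theta 4–8, alpha 8–12, beta 12–30,
low-gamma 30–60, high-gamma 60–80 Hz, averaged over the electrodes of eight
scalp regions and over three task phases (attention 0–500 ms, encoding
500–1,000 ms, retention 1,000–2,000 ms after the cue arrow).

**Cowan's K.** VWM capacity K = load × (hit rate − false-alarm rate) from
the change-detection trial log, per load condition (2 or 4 items).

## Worked example

Simulate a paired pre/post cohort of 20 subjects in which the post session
reduces occipital gamma amplitude and coupling depth by a known per-subject
effect, with capacity improving in proportion:

```python
from tgcwm.pipeline import simulate_cohort, cohort_stats

cohort = simulate_cohort(seed=1, n_subjects=20)
print(cohort.head(3))
print(cohort_stats(cohort))
```

```
subject  gamma_pre  gamma_post  mi_pre  mi_post  k_pre  k_post
    S01     6.4293      2.2617  0.0069   0.0013   1.04    1.36
    S02     6.4516      3.9715  0.0065   0.0029   1.12    1.28
    S03     6.4515      3.2316  0.0067   0.0018   1.32    1.40

              contrast     test  statistic  p_raw  p_fdr direction
     gamma_post_vs_pre paired_t   -15.6187 0.0000 0.0000  negative
        mi_post_vs_pre paired_t   -24.0972 0.0000 0.0000  negative
delta_gamma_vs_delta_k spearman    -0.4214 0.0643 0.0643  negative
```

Each row of `cohort` is one subject: left-occipital high-gamma power (μV²),
retention-phase PAC MI between left-frontal theta phase and left-occipital
gamma amplitude, and Cowan's K (2-item condition), per session. The paired
t-tests recover the injected post-session reductions in gamma power and
coupling, and the Spearman correlation recovers the injected negative
relationship between gamma change and capacity change.

The same stages are scriptable from a shell:

```sh
tgcwm synth --seed 42 --out-dir session/          # EEG + behavior to disk
tgcwm all --config run.json --seed 42 --out run/  # full pipeline -> CSV tables
tgcwm stats --run-dir run/                        # paired contrasts + BH-FDR
```

`tgcwm all` writes `band_power.csv` (one row per subject × session ×
condition × phase × region × band), `coupling.csv` (MI and PPC per
region pair, gamma sub-band and phase window), `behavior.csv` (accuracy,
mean RT, K) and `provenance.json`.

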