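# Methods

## Scope and data model

`tgcwm` analyzes multi-channel EEG from a lateralized change-detection
working-memory task. A continuous `Recording` (channels × time, μV, with
event markers at cue-arrow onsets) is cleaned and cut into 3-s epochs
spanning −1,000…+2,000 ms around the arrow. Within each epoch three task
phase windows are analyzed: attention (0–500 ms after the arrow, i.e. the
arrow/blank interval), encoding (500–1,000 ms, the memory array), and
retention (1,000–2,000 ms, the delay). All aggregation is per
(subject, session ∈ {pre, post}, condition ∈ {2T, 4T}, phase, region).

The eight scalp regions are fixed electrode lists on the 10-10 montage
(left/right frontal, central, temporal, occipital; 46 electrodes in
total); midline sites belong to no region. Any montage/region map can be
supplied as long as every region electrode resolves by name.

## Preprocessing

Stage order is fixed and recorded in the provenance log:

1. **Segment rejection.** The continuous record is scanned in 2-s
   segments; a segment whose RMS (over all channels and samples) is
   strictly greater than 5× the mean segment RMS is excised, and events
   inside it are dropped. "Intensity" is operationalized as RMS because it
   is the standard amplitude proxy; the strict inequality makes the 5×
   boundary well-defined and testable. The rule is idempotent on data
   whose surviving segments are homogeneous.
2. **Filtering.** Zero-phase (forward-backward) 4th-order Butterworth
   band-pass 0.5–95 Hz plus 2nd-order IIR notches at 50 and 100 Hz
   (Q = 30). Zero-phase application matters because Hilbert phase
   estimates feed the coupling stage. Measured attenuation: >20 dB at
   50 Hz, <1 dB at 6/10/40 Hz.
3. **Optional ICA.** Decomposition is delegated to mne's FastICA.
   Components are removed when blink-like (spectrum dominated by <4 Hz
   power *and* topography concentrated on frontal electrodes at twice
   their montage share) or muscle-like (>60% of power above 20 Hz). The
   stage is off by default — the synthetic generator does not produce
   blink/muscle topographies, so running ICA there only costs rank — and
   any decomposition failure passes the data through with a logged
   warning.
4. **Epoching.** One epoch per surviving arrow marker; epochs whose
   window would cross the recording edge are dropped and logged; epochs
   with any |sample| > 100 μV on any channel are masked out (kept in the
   array so trial indices stay stable). The amplitude check runs after
   filtering. The 2-s artifact scan applies to the continuous record and
   the ±100 μV rule to the cut epochs; these are distinct steps, not two
   descriptions of one step.

## Spectral analysis

Spectra use a 2-s analysis window, giving a 0.5 Hz grid. Phase windows
(0.5 or 1 s) are Hann-tapered and zero-padded to 2 s; the taper is
normalized to unit mean-square gain and powers are normalized by the
effective (non-padded) window length, so the sum of all spectral bins
equals the mean-square amplitude of the tapered window exactly
(Parseval). Band power is the sum over bins with low ≤ f < high;
half-open edges make the six bands a partition despite shared printed
edges. Powers are absolute (μV²), not relative. The Hann taper is a
package choice to limit leakage across the narrow theta band; an
untapered path (`taper=None`) exists and is what the exact Parseval
checks use. Whether per-phase spectra should instead use Welch averaging
over whole epochs is left as a config choice at call sites; zero-padding
was chosen as the default because it preserves the 0.5 Hz grid while
respecting phase-window boundaries.

## Coupling

Theta phase and gamma amplitude/phase come from 4th-order zero-phase
band-pass plus Hilbert transform, computed over the **full 3-s epoch**
and then sliced into phase windows — this avoids filter edge effects
inside the short windows and satisfies the ≥3-cycles-of-4-Hz minimum
that a 500-ms window alone would violate.

- **MI (phase-amplitude).** 18 phase bins of 20° starting at −180°,
  half-open; amplitude assigned sample-wise by instantaneous phase;
  P_i = (mean amplitude in bin i) / Σ_j (mean amplitude in bin j); MI is
  the KL divergence of P from uniform over log 18. Empty bins get mass 0
  and contribute 0 (the 0·log 0 limit). All-zero amplitude is an error.
- **PPC (phase-phase).** n:m phase-locking value
  |mean exp(i(n·φ_fast − m·φ_slow))|, default 1:6 (≈6 Hz theta against
  ≈36 Hz gamma). The estimator and (n, m) are package conventions —
  recorded in the output's `nm` column — since no single field standard
  exists; both are configurable.
- **Regional coupling.** Theta phase from the phase-region's
  electrode-averaged signal, gamma amplitude separately for low (30–60)
  and high (60–80) gamma from the amplitude-region's average. MI and PPC
  are computed per epoch within each phase window, then averaged over
  kept epochs (per-epoch-then-average keeps trial-level variance
  available to the stats stage; concatenation would not). Windows
  shorter than two 4-Hz cycles (500 ms) are flagged `low_confidence`.

**Estimator bias.** MI on pure noise is positive and shrinks with window
length, so the 1,000-ms retention window has a lower null MI than the
500-ms attention window. Comparisons should therefore be made within a
window, never across window lengths; the test suite asserts the bias
direction so it stays documented.

## Behavior

Hit rate = P(respond "match" | match trial); false-alarm rate =
P(respond "match" | mismatch trial); K = load × (hit − fa). Accuracy is
computed over responded trials (omissions excluded from the
denominator), and mean RT over correct responded trials — the usual
convention in change-detection work; a switch (`rt_correct_only=False`)
includes error trials. Cells with no mismatch (or no match) trials raise,
since the rates are undefined.

## Statistics

Two-sample contrasts use Student's t for normal data and Mann-Whitney U
otherwise, gated automatically by per-group Shapiro-Wilk at α = 0.05
(the gate is a documented heuristic; any test can be forced).
Pre/post contrasts use paired t-tests; categorical tables use Pearson's
χ²; brain-behavior relationships use Spearman correlations on
per-subject change scores (post − pre). All tests are two-sided.
Benjamini-Hochberg FDR adjustment (statsmodels' step-up implementation,
monotone-enforced, capped at 1) is applied within analysis families —
power contrasts, coupling contrasts, behavior, correlations — with the
family recorded in the output; the family structure is a package
convention. Degenerate inputs (zero variance in both groups, zero-variance
paired differences) raise rather than returning a meaningless p.

## Synthetic data

The generator emulates the study conditions, not arbitrary EEG:

- **Task.** 100 trials per condition (2-item and 4-item) by default, one
  marker per trial at the arrow onset, conditions interleaved in random
  order. Inter-trial spacing is jittered uniformly in [3.5, 4.5] s — the
  interval is a declared default (the task literature does not pin one
  down), chosen so that −1…+2 s epochs can never overlap.
- **Coupled signal.** A shared theta oscillator (default 6 Hz, 10 μV)
  drives frontal channels; occipital channels carry gamma (default 40 Hz,
  5 μV) whose envelope is (1−d) + d·(1+cos φ_θ)/2 at per-channel depth d,
  plus an attenuated local theta. The cosine envelope is the canonical
  phase-amplitude test signal and yields closed-form phase-bin masses,
  which is what makes exact MI oracles possible.
- **Noise.** 1/f ("pink") background (default SD 2 μV) plus white
  measurement noise (default SD 1 μV), per channel. The pink component
  makes band-power code face a realistic spectral slope.
- **Artifacts.** Each 2-s segment is scaled by `artifact_gain` (default
  10×) with probability `artifact_rate`; injected segment indices are
  kept in the ground truth for recovery tests.
- **Behavior.** Balanced match/mismatch truth per condition (shuffled),
  responses binomial at the configured hit/false-alarm rates (defaults
  0.90/0.10 for 2-item and 0.75/0.20 for 4-item — typical old-adult
  change-detection performance), lognormal RTs (μ = 6.6, σ = 0.25 in
  log-ms, ≈735 ms median; only mean RT is analyzed downstream).
- **Determinism.** One integer seed; identical config + seed gives
  bit-identical recordings and logs.

What the generator does **not** emulate: volume conduction / realistic
topographies, event-related potentials, blink or muscle waveforms
(artifacts are plain gain steps), non-stationary coupling, or any
dependence of the EEG on trial content. Passing tests therefore show the
*pipeline* recovers what was injected under realistic noise; they do not
certify performance on real recordings with correlated sensor noise and
physiological artifacts.

## Cohort simulation and problem sizes

`simulate_cohort` builds the paired-design validation cohort: 20
subjects, each with a per-subject effect drawn uniformly from [0.2, 0.8]
that scales down post-session occipital gamma amplitude (injected at
65 Hz, in the high-gamma band) and coupling depth, while raising the
2-item hit rate by 0.35 × effect from a 0.70 baseline (kept off ceiling
so capacity change remains informative). This makes the post−pre gamma
change negatively related to the capacity change by construction.
Per-subject recordings use a reduced 6-channel left-frontal +
left-occipital montage at 250 Hz with 6 trials per condition — enough
epochs for stable paired contrasts at n = 20 — while behavior keeps the
full 100 trials per condition. These sizes are the package's validation
defaults; all of them are parameters.

## Numerical conventions

- Phase bins and band edges are half-open; phase +π folds into the last
  bin.
- Exactly 5× mean RMS is retained (strict inequality for removal);
  exactly ±100 μV is kept (strict exceedance for rejection).
- Band-pass filters are applied forward-backward, so effective orders
  are doubled and group delay is zero.
- BrainVision output stores INT_16 at 0.1 μV resolution (range ±3,276 μV);
  the EDF writer uses 16-bit records with integer physical bounds and
  1-s records (integer sampling rates only), and carries no events.
- Seeds below 2³¹; all generator randomness flows through
  `numpy.random.default_rng`.

## Known limitations

- The PPC estimator and its (n, m) ratio are conventions; reported PPC
  values are not comparable across different (n, m).
- MI magnitudes depend on window length (bias above) and on the amount
  of data per epoch; only within-design comparisons are meaningful.
- No surrogate-based significance for MI in the headline pipeline;
  phase-shuffled nulls would be the natural extension.
- No bad-channel interpolation or re-referencing; recordings are
  analyzed in their recorded reference.
- No time-frequency (wavelet/multitaper) decompositions or comodulogram
  sweeps; bands are fixed a priori.
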