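# Methods

`l2speech` implements the acoustic-measurement and statistical-inference
chain of a two-group (active vs. sham), pre/post speech-training study of
second-language (L2) English: vowel formants by linear predictive coding
(LPC), consonant spectral centre of gravity (COG), perceptual-judgment
exclusion, sex normalization, difference/distance scoring, and two-group
MANOVA inference. Because no raw recordings ship with the package, a
synthetic-study generator produces audio tokens with exact acoustic ground
truth, so every measurement stage is validated by parameter recovery rather
than by fixture files.

## The synthetic study

**Design.** 36 participants (18 active / 18 sham, sexes balanced), two
sessions (pre, post), seven phoneme contrasts — three vowel (/i/-/ɪ/,
/ɛ/-/æ/, /ʌ/-/ɑ/) and four consonant (/z/-/ð/, /d/-/ð/, /s/-/θ/, /t/-/θ/) —
five word tokens per phoneme (35 minimal pairs, 70 words), three
repetitions per word per session. These defaults give 6480 vowel and 8640
consonant tokens; counts are closed-form products of the design and are
asserted as invariants. Phonemes carry ASCII ARPABET-style codes
(`iy ih eh ae ah aa`, `z dh d th s t`). Because /dh/ and /th/ each occur in
two contrasts, word identifiers embed the contrast name.

**Vowel synthesis.** A stationary vowel is an impulse train at the
fundamental, shaped by a two-pole glottal lowpass (−12 dB/oct above
100 Hz), passed through a cascade of second-order resonators — one per
formant — so the poles of the synthesis filter are exactly the specified
formant frequencies and bandwidths (the cascade, not parallel, form is used
precisely because its poles are the formants). Four formants are rendered
(F3/F4 fixed defaults) so that LPC orders 8–10 (≈ 2 × formants + 2) are
well conditioned. Default F2 targets per category are the study's
pre-training means averaged over the two groups (2585, 2322, 2130.5, 1995,
1600, 1391.5 Hz for /i, ɪ, ɛ, æ, ʌ, ɑ/); F1 defaults are standard American
English reference values (310–750 Hz). Specs are on the female scale; male
tokens divide F1 by 1.183 and F2–F4 by 1.172 (the inverse of the fixed
normalization constants) and use a lower fundamental (120 vs. 210 Hz,
jittered 3% per token). Speaker identity is a per-participant
multiplicative offset (4% sd) on formant targets, constant across sessions;
token scatter is 2% sd. Durations are drawn from a normal (150 ± 30 ms)
clipped to 80–250 ms — a convention, the source study does not report
duration distributions — and snapped to the sample grid.

**Consonant synthesis.** A consonant token is band-limited noise: a band
filter from `band_low` to `band_high` whose amplitude follows a dB/octave
tilt across the band. Synthesis is random-phase spectral synthesis — the
token's magnitude spectrum *is* the designed response, phases are uniform —
so the measured COG of even a 30 ms burst matches the analytic oracle to
well under 1%. (A Gaussian-noise realization would put ≈2% sampling noise
on a 200 ms token's COG; envelope-exact synthesis keeps the oracle
noise-free, which is the point of a validation generator.) The ground-truth
COG is the closed-form power-weighted mean frequency of the filter
response, with weight exponent p = 2: for |H(f)| = (f/f_lo)^β on
[f_lo, f_hi], COG = [∫ f^{2β+1} df]⁻¹ ∫ f^{2β+2} df. Sibilants sit high
(/s/: 3.5–7.8 kHz), dentals low and diffuse, stops are short bursts.
Token-to-token COG variability enters through lognormal band-edge jitter
(3% sd) and a per-speaker band offset (5% sd).

**Behavior.** AXB discrimination trials are Bernoulli draws at a
per-contrast baseline probability, shifted (default +0.12 to +0.15) only in
the active-group post session for a subset of contrasts — mirroring the
direction of the study's effects; magnitudes are free generator parameters,
not estimates. Reaction times are truncated normal (900 ± 250 ms on
[200, 2500]); trials lapse (RT missing) at rate 0.02. Musical-task scores
are generated as participant-level ability plus noise with no group effect.
Consonant judge labels use the study's scheme: two primary judges, a third
on disagreement, each mislabelling (as the contrast partner) at a
configurable rate; the default 0.048 puts the expected two-judge-majority
discard fraction near the study's 0.7% (P(discard) = e²(3 − 2e)).

## Measurement

**Formants.** Vowels are anti-alias filtered and resampled
(`scipy.signal.resample_poly`) to 8 kHz (men) or 11 kHz (women),
pre-emphasized with a first-difference filter referenced at 50 Hz, and
analysed in 25 ms Gaussian-windowed frames at a 6.25 ms step. Each frame is
fitted with the Burg method (in-package recursion, verified against an
independent implementation to machine precision) at order 8 (men) or 10
(women). Roots r of the prediction polynomial map to candidates with
frequency = arg(r)·fs/2π and bandwidth = −ln|r|·fs/π; candidates are
retained iff frequency > 90 Hz and bandwidth < 400 Hz (both strict — the
boundary handling is a package choice) and frequency is at least 50 Hz
below Nyquist. F1/F2 are the means of the two lowest retained candidates
over frames whose centres fall in the 30 ms window centred on the vowel
midpoint (vowels shorter than 30 ms use all frames; a single-central-frame
mode exists). Assignment is positional per frame; there is no continuity
tracking. Frame length, step, window and pre-emphasis are conventional
defaults of this analysis style and are all configurable. An override table
(token id → LPC order, even, 4–16) re-analyses listed tokens and records
the order used — the batch stand-in for interactive visual correction.

**COG.** One unwindowed transform of the whole annotated consonant segment
at the native rate (no sex-specific downsampling — sibilant energy above
5.5 kHz must be retained), COG = Σ f·|S(f)|^p / Σ |S(f)|^p with p = 2, DC
included. Hann windowing and Welch averaging are options; full-band,
unwindowed is the default. Segments under 32 samples or all-zero are
flagged missing, not errors.

## Scoring

Consonant rows are kept iff ≥ 2 judges labelled the target; the exclusion
report gives the discard percentage at one decimal. Male F1/F2 are
multiplied by the fixed factors 1.183/1.172 (female/male mean ratios);
estimating the factors from data is opt-in, and a provenance flag guards
against double application. Accuracy is percent correct of attempted
trials; RT averages correct, non-missing trials. Token-level measures
reduce to participant × session × variable means; then difference =
post − pre and distance = |difference|. The sign convention (positive =
increase) is one configuration point; the reversed convention is available.

## Inference

`TwoGroupManova(endog, groups).fit()` returns Wilks' Λ = det(E)/det(E+H)
with the exact two-group transform F = ((N−p−1)/p)(1−Λ)/Λ on (p, N−p−1)
degrees of freedom — exact for two groups, hence the df patterns F(3,32)
and F(4,31) at N = 36 — plus univariate follow-up ANOVAs (one-way F on
(1, N−2), equal to the squared pooled t). `manova_family` wraps the full
chain: an advisory inter-correlation prescreen (warn, don't abort, when any
pairwise |r| ≤ 0.30), the multivariate test, follow-ups, and per-group
one-tailed one-sample t-tests of mean change against zero (direction:
improvement > 0 under the default sign convention). The blinding check is a
Pearson χ² of independence on the 2×2 group × guess table with **no**
continuity correction (the uncorrected statistic reproduces the reference
value 0.45 on counts 11/7 vs 9/9; Yates would give 0.11). Baseline
diagnostics report the point-biserial correlation of group with pre-test
scores, pre/post reliability, and a baseline t-test per variable. Missing
cells are excluded listwise per analysis. Degenerate inputs: an all-zero
change vector yields t = 0, p = 0.5 (no evidence) rather than an error;
zero variance around a nonzero effect raises.

## Validation scales and what passing shows

The test suite and `scripts/acceptance.py` run the generator at the full
published design for token bookkeeping (counts only, no audio), ~120
rendered vowels for formant recovery, ~60 fricatives for COG recovery, and
1000 replicates of the null behavioral chain for type-I calibration of the
MANOVA at N = 36 — sizes chosen so the whole validation runs on a laptop in
about a minute. Passing shows the measurement chain recovers known
synthesis parameters and the inference chain is calibrated on the
generator's data. It does not show robustness to what the generator omits:
coarticulation and formant transitions, nasalization, channel noise,
f0 tracking errors, non-stationary fricatives, or behavioral learning
within a session.

## Known limitations

- **F1 at high fundamentals.** With f0 ≈ 210 Hz, harmonics sample the F1
  region too sparsely and Burg LPC shows the well-documented oscillating F1
  bias (up to ±10% for F1 ≈ 300 Hz, depending on where harmonics fall).
  Median recovery error across categories and sexes stays ≈ 2%, but
  single-token F1 near 300 Hz at female f0 should be read with that bias in
  mind; the same limitation applies to real recordings analysed this way.
- Tokens are isolated target segments padded with silence, not words;
  segmentation is taken as given (the source workflow segmented manually).
- The TextGrid reader supports the full text dialect only (UTF-8, or UTF-16
  with BOM); the short dialect is rejected with an explicit message.
- MANOVA requires each group larger than the number of dependent variables;
  six-variable families need at least 7 participants per group.
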