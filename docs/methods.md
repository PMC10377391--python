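# Methods

## Problem setting

Substitution voicing after total laryngectomy (esophageal,
electrolarynx, tracheoesophageal) produces speech with three
characteristic degradations: aperiodicity of the source, involuntary
phonatory breaks, and strong additive noise. `voicegate` targets the
third: removing stationary background/additive noise from short
isolated-word recordings (counting, test sentences) without altering
the voiced material itself, so that downstream clinical measures of
voicing quality are preserved rather than artificially inflated.

## Analysis–synthesis

The short-time Fourier transform uses a periodic Hann window of 2048
samples and a hop of 512 (46 ms / 75 % overlap at the 44.1 kHz
reference rate; the implementation is rate-agnostic). The clip is
reflect-padded by half a window so frame `t` is centered on sample
`t·hop`; the frame count is `1 + floor(len/hop)`. Synthesis is weighted
overlap-add with squared-window normalization, which is an exact
inverse for windows satisfying the constant-overlap-add condition at
the chosen hop; the configuration is checked (flatness of the
overlap-added squared window within 1e−10 away from the edges) and a
non-compliant window/hop pair is rejected rather than silently
distorting. Phase is carried end-to-end: the gate scales complex cells,
and the NMF stage replaces magnitudes while reusing the phase of the
masked spectrogram; no iterative phase estimation is performed.
Measured round-trip error is at machine precision (~1e−16 relative
RMS), far inside the 1e−6 contract.

## Spectral noise gate

Per-bin statistics of the dB magnitude (`20·log10(|S| + 1e−10)`) give a
threshold `T_f = μ_f + n_std·σ_f` with `n_std = 1.5` by default; cells
strictly above their bin's threshold count as signal, ties and below as
noise. dB rather than linear magnitude keeps σ meaningful across the
~60 dB dynamic range between voiced cells and the noise floor.

**Noise statistics come from the quietest fifth of frames.** The gate
needs an estimate of the *noise* distribution per bin. When a separate
noise-profile clip is available it is used directly; otherwise the
frames whose broadband energy lies at or below the 0.2 quantile —
inter-word pauses and phonatory breaks — serve as a self-estimated
noise profile. Estimating the statistics over *all* frames instead
makes the threshold a per-bin outlier detector: on material that is
voiced most of the time, every bin's own mean sits near the speech
level and the mask suppresses essentially everything (we measured
output SNR collapsing to ~0 dB regardless of sensitivity). The quantile
estimator is the standard noise-profile practice and reduces to the
same statistics when the clip is mostly noise. The quantile (0.2) is
deliberately below the pause fraction of isolated-word speech so that
the profile stays noise-dominated.

The binary mask is smoothed by convolution with a separable unit-sum
triangular kernel spanning 4 bins × 8 frames (≈86 Hz × 93 ms at the
default analysis), wide enough to avoid abrupt gain jumps, narrow
enough to preserve break boundaries. The soft gain
`1 − prop_decrease·(1 − M_smooth)` with `prop_decrease = 1` fully
suppresses pure-noise cells; the gate never amplifies, and raising
`n_std` can only shrink the signal set.

## Pareto-optimized NMF

The masked magnitude spectrogram is approximated as `V ≈ W H` by
multiplicative updates for the L1-penalized Frobenius objective

    H ← H ⊙ (WᵀV) ⊘ (WᵀWH + λ + ε),   W ← W ⊙ (VHᵀ) ⊘ (WHHᵀ + ε)

with ε = 1e−12, seeded uniform initialization scaled by
`sqrt(mean(V)/k)`, and stopping when the relative objective change
falls below 1e−6 (or 200 sweeps). After each sweep the columns of `W`
are rescaled to unit L2 norm, with the scale absorbed into `H`. This
leaves `W H` — and therefore the unpenalized objective and its
monotone-decrease guarantee — unchanged, but is essential for the
sparsity penalty to mean anything: the factorization is invariant under
`W → cW, H → H/c`, so without a scale pin the optimizer can shrink
`λ‖H‖₁` indefinitely at constant fit and the sparsity weight has no
stable effect on the *shape* of `H` (we measured ~40 % non-monotone
sparsity-vs-λ outcomes without the pin, and none with it).

Candidates are swept over `k ∈ {2,4,8,16}` × `λ ∈ {0, 0.01, 0.1, 1}`
(per-candidate seeds offset by 1000·index for reproducibility) and
scored on three normalized, minimized objectives: relative
reconstruction error `‖V−WH‖_F/‖V‖_F`, activation density
`1 − hoyer(H)` (Hoyer sparsity: 0 for all-equal entries, 1 for a single
nonzero), and complexity `k/k_max`. The Pareto front is computed by
exact pairwise dominance; the selected compromise is the front member
nearest (Euclidean) to the ideal point after per-objective min–max
normalization across the front, with ties broken toward smaller rank,
then smaller λ, then sweep order. An exhaustive grid rather than an
evolutionary multi-objective search keeps the procedure deterministic
and testable at this scale. Multiplicative updates can stall in local
minima on sparse targets (e.g., exactly diagonal matrices); the package
does not restart automatically, but restarts are a seed change away and
the test suite documents the behavior.

## Synthetic alaryngeal fixtures

Because no real alaryngeal recording comes with a clean reference, the
generator builds one: a harmonic source (harmonics to 4 kHz, 1/h
rolloff) whose fundamental (110 Hz default) is perturbed once per
glottal cycle by Gaussian jitter (3 % default), mixed with aspiration
noise at a 10 dB harmonics-to-noise ratio, shaped by three two-pole
formant resonators (500/1500/2500 Hz), and amplitude-gated twice:
utterances of 250–450 ms separated by 350–650 ms pauses emulate the
isolated-word/counting material used in clinical assessment, and
phonatory breaks (1 per second expected, 50–200 ms, 5 ms raised-cosine
ramps) emulate the involuntary interruptions of substitution voicing.
The degraded companion adds white (or pink) noise scaled so the
clip-level SNR is met exactly; both signals share one peak-normalization
gain and remain sample-aligned. The fixed evaluation panel crosses
SNR ∈ {0, 5, 10} dB with breaks on/off (white noise), six pairs, all
seed-derived.

What the generator does *not* model: articulation and phonetic content,
the spectral envelope dynamics of real words (each utterance is a
sustained-vowel burst), reverberation, non-stationary noise, and the
perceptual qualities of TEP voice. Passing the panel therefore
demonstrates that the pipeline removes stationary additive noise from
pause-structured voiced material without damaging voicing evidence — it
does not demonstrate intelligibility gains on real patients.

## Metrics and statistics

Waveform SNR is `10·log10(Σref²/Σ(ref−est)²)` (capped at 300 dB), a
deliberately strict measure that counts any speech distortion as noise.
The voicing-evidence proxy (30 ms frames, 10 ms hop; voiced iff RMS
> 0.01 and max normalized autocorrelation over 60–400 Hz lags > 0.45)
is a fixture-calibration instrument for synthetic material, not a
clinical voicing analyzer; its thresholds are documented constants.

The inference layer reproduces clinical-table statistics from printed
summaries: pooled and Welch t-tests from (mean, SD, n) triples with
exact SE/df/CI formulas, mean-centered Levene's test, Pearson's
chi-squared for 2×2 tables (optional Yates correction), and half-up
rounded percentages. Recomputing the pooled rows from the published
75-vs-75 group summaries reproduces the published t statistics and
standard errors to within 0.5 % (the printed inputs are rounded to 2–4
significant figures); the published average-voicing-evidence row is too
coarsely rounded (means 0.81 vs 0.80) for a meaningful recomputation
and is reported but not asserted. Levene's statistics require raw
samples and are only checked against the definition, not against
published values.

## Numerical and degenerate-input choices

- Mask ties go to noise, so an all-constant spectrogram is
  deterministically all-noise and silence maps to silence.
- Single-frame spectrograms get σ = 0 with a warning rather than NaN.
- An all-zero masked spectrogram short-circuits the NMF stage.
- The SNR of a zero estimate is 0 dB by construction; a perfect
  estimate reports the 300 dB cap instead of infinity.
- All randomness flows through `numpy.random.default_rng` seeds;
  identical inputs and seeds give bit-identical factors, selections and
  output files.

## Problem sizes

Unit tests run at 8–16 kHz with sub-second clips and small matrices;
the acceptance script uses the generator defaults (44.1 kHz, 2 s
clips), 100 round-trip clips, and the full six-fixture panel, and
completes in well under a minute on one CPU.
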