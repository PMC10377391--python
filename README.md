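# voicegate

Noise reduction for **alaryngeal (substitution-voicing) speech** — the
voice produced after total laryngectomy with esophageal speech, an
electrolarynx, or a tracheoesophageal prosthesis (TEP). Such voices are
marked by aperiodicity, involuntary phonatory breaks and prominent
additive noise, which degrade intelligibility, most painfully on the
phone or in noisy rooms. `voicegate` cleans these recordings in two
stages and ships everything needed to evaluate the result without any
patient data: a synthetic alaryngeal-speech generator with a clean
ground-truth reference, signal metrics, and the summary-statistics
machinery used in clinical comparisons of original vs. enhanced
recordings.

## Method

**Stage 1 — spectral noise gate.** The clip is analyzed with a
short-time Fourier transform (Hann window 2048, hop 512, centered). For
each frequency bin `f` the gate computes the mean `μ_f` and standard
deviation `σ_f` of the dB magnitude over the noise-dominated frames
(the quietest 20 % of frames — the inter-word pauses — or an explicit
noise-profile clip), and thresholds

    T_f = μ_f + n_std · σ_f            (n_std = 1.5 by default)

Cells with `D[f,t] > T_f` are flagged signal (1), the rest noise (0).
The binary mask is smoothed with a separable unit-sum triangular kernel
(4 bins × 8 frames) and applied as a soft gain
`G = 1 − prop_decrease · (1 − M_smooth)` to the complex spectrogram,
phase untouched.

**Stage 2 — Pareto-optimized NMF.** The masked magnitude spectrogram
`V = |S_mod|` is factorized as `V ≈ W H` (`W, H ≥ 0`) by multiplicative
updates minimizing `‖V − WH‖_F² + λ‖H‖₁`, over a grid of ranks
`k ∈ {2, 4, 8, 16}` and sparsity weights `λ ∈ {0, 0.01, 0.1, 1}`. Every
candidate is scored on three minimized objectives — relative
reconstruction error, activation density `1 − hoyer(H)`, and model
complexity `k/k_max` — the Pareto front (mutually non-dominated set) is
extracted, and the compromise closest to the ideal point is selected.
The clean spectrogram `W H · e^{i·arg(S_mod)}` is inverted by weighted
overlap-add back to a waveform.

The gate-only variant (`skip_nmf`) is exposed as an ablation; the two
pipelines differ by exactly the NMF stage.

## Worked example

```python
import voicegate as vg
from voicegate.evalstats import snr_db, voicing_evidence_proxy

pair = vg.generate(vg.SynthSpec(duration=2.0, snr_db=5.0, seed=3))
cleaned, report = vg.clean(pair.degraded, vg.PipelineConfig(seed=3))
print(f"input SNR:   {snr_db(pair.clean, pair.degraded):5.2f} dB")
print(f"cleaned SNR: {snr_db(pair.clean, cleaned):5.2f} dB")
sel = report.selected
print(f"selected NMF: k={sel['k']}, lambda={sel['lambda']}, "
      f"recon error={sel['objectives']['f1_recon']:.3f}")
```

prints

```
input SNR:    5.00 dB
cleaned SNR: 13.60 dB
selected NMF: k=8, lambda=0.01, recon error=0.096
```

The generator built a 2 s utterance-structured alaryngeal-like clip
(jittered harmonic source, formant filtering, phonatory breaks) plus
white background noise at exactly 5 dB SNR; the pipeline raised the SNR
against the retained clean reference by 8.6 dB, and the model-selection
step settled on a rank-8 factorization with a light sparsity penalty.
The voicing-evidence proxy is unchanged (0.29 before and after): the
gate removes noise between words without eroding the voiced segments.

The same pipeline is available from the shell:

```sh
voicegate synth demo.wav --snr-db 5 --seed 3          # demo_clean.wav + demo_degraded.wav
voicegate clean demo_degraded.wav demo_cleaned.wav --report report.json
voicegate eval demo_clean.wav demo_degraded.wav demo_cleaned.wav
voicegate stats summaries.csv --counts 4 72 10 65 --out stats.json
```

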