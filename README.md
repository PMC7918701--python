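# ssvepdecode

Frequency recognition for SSVEP-based brain–computer interfaces.

In an SSVEP speller, a subject gazes at one of `Nf` targets flickering at
distinct frequencies; the steady-state visual evoked potential measured over
occipito-parietal EEG channels oscillates at the gazed frequency and its
harmonics, and decoding reduces to identifying that frequency from a short
multichannel window `X̄ ∈ ℝ^{Nc×Ns}`. This package implements and compares
four recognizers, their filter-bank variants, a synthetic SSVEP generator,
and a leave-one-block-out evaluation harness, so the whole pipeline runs and
is testable without any recorded dataset.

## Methods

**CCA.** Score class *i* by the largest canonical correlation
`ρ_i = max_{wx,wy} corr(wxᵀX̄, wyᵀZ_i)` against the sinusoidal reference
`Z_i ∈ ℝ^{2Nh×Ns}` of stacked `sin(2πh f_i t), cos(2πh f_i t)` harmonics;
predict `argmax_i ρ_i`.

**Extended CCA.** Add the subject's individual templates
`Y_i = (1/Nt) Σ_t X_i^{(t)}` (trial averages of the training blocks). Three
CCA weight pairs — for (X̄, Z_i), (X̄, Y_i) and (Y_i, Z_i) — give spatial
filters; four projected Pearson correlations `r_1..r_4` between the test
trial and `Z_i`/`Y_i` are fused as `ρ_i = Σ_k sign(r_k) r_k²`.

**TRCA.** Learn, per class, the channel weight vector maximizing inter-trial
reproducibility: `ŵ = argmax_w (wᵀSw)/(wᵀQw)`, where `S` sums the
cross-covariances over all ordered pairs of training trials and `Q` is the
covariance of the concatenated trials — the leading eigenvector of
`Q⁻¹S`. Score class *i* as `ρ̂_i = corr(w_iᵀX̄, w_iᵀY_i)`.

**Two-step TRCA (TSTRCA).** Reuse the whole filter set as an ensemble. For
each candidate class *i* build
`β_i = (corr(Y_i, X̄), corr(w_1ᵀY_i, w_1ᵀX̄), …, corr(w_NfᵀY_i, w_NfᵀX̄))`
— the same template/test pair through every class's filter, plus one
unfiltered matrix correlation — and fuse
`ρ̃_i = Σ_{k=0}^{Nf} sign(β_{i,k}) β_{i,k}²`. The ensemble averages over
many independently-estimated filters and is what preserves accuracy at
short analysis windows.

**Filter bank.** Optionally decompose the epoch into nested sub-bands
`[8b, 90]` Hz (b = 1..Nb), run the base method per band, and combine with
weights `s_b = b^{-1.25} + 0.25`:
`ρ_i = Σ_b s_b · sign(r_i^b) (r_i^b)²`. Method tags `fbtrca`, `fbtstrca`.

**Evaluation.** Block-wise leave-one-out: each of the `Nt` recorded blocks
is held out once; accuracy and the information transfer rate

    ITR = [log₂Nf + P log₂P + (1−P) log₂((1−P)/(Nf−1))] · 60/T   bits/min

(with `T` = window length + 0.5 s gaze shift) are averaged over folds, plus
macro precision/recall/F1 from the pooled confusion matrix.

## Worked example

```python
from ssvepdecode import SimConfig, simulate_subject, EvalConfig, loocv

subject = simulate_subject(SimConfig(mixing_seed=1, noise_seed=2))
for method in ("cca", "extcca", "trca", "tstrca"):
    res = loocv(subject, method, EvalConfig(tw_s=0.3))
    print(f"{method:8s} accuracy={res.accuracy:.3f}  "
          f"ITR={res.itr_bits_per_min:6.1f} bits/min  F1={res.f1:.3f}")
```

```
cca      accuracy=0.188  ITR=   9.7 bits/min  F1=0.173
extcca   accuracy=0.604  ITR=  70.7 bits/min  F1=0.595
trca     accuracy=0.812  ITR= 139.7 bits/min  F1=0.810
tstrca   accuracy=0.938  ITR= 191.5 bits/min  F1=0.937
```

One simulated subject (8 targets at 8.0–9.4 Hz, 9 channels, 6 blocks,
−10 dB in-band SNR over pink noise plus a spontaneous alpha rhythm) is
decoded from 0.3 s windows. Sinusoid-referenced CCA is barely above the
1/8 chance level because the alpha rhythm overlaps the stimulation band;
template-based methods recover most trials, the TRCA spatial filter
suppresses the alpha topography, and the two-step ensemble adds a further
margin — the qualitative ordering this method family shows on real
recordings.

The same pipeline is scriptable from the shell:

```sh
ssvepdecode simulate --out subject.h5 --seed 1
ssvepdecode evaluate --in subject.h5 --method tstrca --tw 0.3 --out-dir run/
```

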