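# segvoice

Continuous emotion classification from the voice, one fixed 1.5 s window
at a time.

`segvoice` is for researchers in affective computing and computational
psychology who want to score emotion along an audio stream without
segmenting it into semantically coherent utterances first. Every
recording — or every window of a longer stream — is forced to a uniform
1.5 s duration (symmetric trim or silence padding), described by a
14,244-entry acoustic feature battery and/or a 320×240 RGB spectrogram,
and classified into six categories (anger, disgust, fear, joy, sadness,
neutral) by one of three designs:

- **DNN** — a feedforward network over the feature vector,
- **CNN** — a convolutional network over the spectrogram image,
- **C-DNN** — a hybrid with both branches concatenated before a softmax
  head.

Evaluation is Bayesian throughout. A classifier's accuracy θ is treated
as a binomial success probability with a conjugate beta prior, so after
*s* correct and *f* incorrect predictions

    θ | data ~ Beta(1 + s, 1 + f),     MAP = s / (s + f)   (flat prior)

Classifiers are compared to a random guesser (chance = 1/6) and to human
listeners via the posterior overlap coefficient ∫ min(f_A, f_B) and
P(θ_A > θ_B). *Independent Validation* makes the posterior prequential:
after training on 10% of the data (with 10% held out for validation),
the remaining stream is consumed in chunks of 16 items, each chunk
predicted **before** it joins the training set, so every update to the
posterior comes from an out-of-sample prediction.

Corpus utilities parse the RAVDESS and Emo-DB filename conventions onto
the six-class label set, and a seeded synthetic-utterance generator
(emotion-dependent pitch, energy, modulation and noise profiles with a
class-separation knob) makes the entire pipeline testable without
external corpora.

## Worked example

The one-command demo generates a balanced synthetic dataset (12 segments
per class), extracts the full feature battery, and runs Independent
Validation with a DNN:

```bash
$ segvoice demo --seed 1 --n-per-class 12 -o demo_out
[1/4] synthesized 72 segments (0.2s)
[2/4] extracted 72 x 14244 features (5.1s)
[3/4] Independent Validation: 30/58 correct, posterior beta(31,29), MAP 0.517
[4/4] P(model > random) = 1.0000 (5.7s total)
```

Reading the numbers: each of the 72 windows became a 14,244-entry feature
vector; 58 items were streamed in chunks of 16 and predicted before
training on them; 30 correct / 28 incorrect updates the flat beta(1,1)
prior to beta(31,29), whose mode (MAP) of 0.517 is the accuracy estimate —
far above the 1/6 ≈ 0.167 chance level, and the probability that the
model outperforms a random guesser is ≈ 1.

The same stages are available individually (`segvoice synth`, `scan`,
`segment`, `features`, `spectrograms`, `train`, `eval-cv`, `eval-iv`,
`compare-human`, `explain`) and as a Python API:

```python
import segvoice as sv

seg = sv.synth_segment("anger", sv.SynthConfig(seed=7), 0)
fv = sv.extract_feature_vector(seg)      # 14,244 named entries
img = sv.render_spectrogram(seg)         # 240 x 320 x 3 uint8
```

Short narrative scripts, one per capability, live in `examples/`.

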