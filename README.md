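# sbpsnn — spiking-network decoding of emotional EEG

`sbpsnn` re-implements, as a tested Python pipeline, an emotional-EEG
decoding analysis built around a three-layer spiking neural network with
local plasticity and *self-backpropagation* (SBP): multichannel EEG is
cleaned, threshold-encoded into binary spike trains, and classified by a
leaky integrate-and-fire (LIF) network whose output synapses learn from a
teaching spike train while the adjustment is mirrored, with separate
long-term-potentiation/-depression proportions, onto the hidden-layer
synapses.  Around the decoder the package provides the full analysis
chain: electrode-subnetwork mining by contribution-ranked elimination,
K-means fusion-model construction, frequency-band biomarker attribution
(per-band decoding and EasyMKL), and directed spectral Granger
connectivity.  Because the original recordings are not public, a
synthetic generator reproduces the statistical structure the analysis
assumes (1/f background, class-conditional band-power effects on chosen
electrodes, directed VAR couplings, blink artifacts), so every stage is
testable end to end.

## The model

**Decoder.**  100 input neurons (threshold-coded ON/OFF streams allocated
round-robin over the analysed electrodes), 200 LIF hidden neurons with a
1:1 excitatory:inhibitory split and Dale sign constraint on their
outgoing weights, and 1 (binary) or 4 (four-class) LIF output neurons.
Weights are initialised by a small-world rule on a 471-node spatial grid
(local links within a radius, 80 % positive, sparse long-range links).

**Learning.**  Synapses carry Tsodyks–Markram short-term plasticity.
During training a regular teaching spike train at rate `r_T` drives the
true-class output; the output-synapse update accumulates the presynaptic
STDP trace mass against the teaching-minus-realised spike-count error
(teacher-driven STDP in rate-coded form), descending the loss

    C = 1/2 * sum_k (u_k − o_k)^2

where `u_k` is the realised output rate normalised by the teaching rate
and `o_k` the expected output.  SBP mirrors the potentiating and
depressing parts of those adjustments onto the active hidden-layer
synapses with proportions `rho_LTP` and `rho_LTD`.  Homeostatic
threshold scaling keeps hidden rates near a target.  A rate-based
two-layer reference network trained by the exact gradient of `C` (the
pure-backpropagation comparison) is included and gradient-checked.

## Worked example

```python
from sbpsnn import EmotionDecoder, TrainConfig
from sbpsnn.tasks import make_emotion_task

task = make_emotion_task(seed=7)          # fear vs neutral, beta effect on P1/P2
tr_x, tr_y, te_x, te_y = task.split()
model = EmotionDecoder(tr_x, tr_y, electrodes=task.electrodes,
                       montage=task.montage, w_decay=0.1)
fit = model.fit(TrainConfig(epochs=60, batch_size=20, teaching_rate=40.0,
                            seed=7))
print(fit.summary())
preds = fit.predict(te_x)
print("test accuracy:",
      100.0 * sum(p == l for p, l in zip(preds, te_y)) / len(te_y), "%")
```

```
Spiking emotion decoder (self-backpropagation SNN)
====================================================
classes:        neutral, fear
architecture:   100 input / 200 hidden / 1 output
E:I hidden:     1:1 (Dale sign constraint on outgoing weights)
SBP:            on (rho_ltp=0.9, rho_ltd=0.6)
epochs/batch:   60 / 20
teaching rate:  40 Hz
final loss C:   0.1157
train accuracy: 72.92 %
test accuracy: 62.5 %
```

The summary reports the fitted decoder: the binary task orders classes
(neutral, fear) so the teaching train drives the emotion class; the
final loss is the mean of `C` over the last epoch; accuracies are
percent correct on the training split and the held-out trials.

The full workflow (simulate → preprocess → encode → train → mine → fuse
→ bands/MKL → Granger) is available as a library call
(`sbpsnn.pipeline.run_pipeline`) and as a CLI:

```bash
sbpsnn all --out run_output --seed 3
```

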