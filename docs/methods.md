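# Methods

## Scope

The package implements an emotional-EEG decoding analysis around a
spiking neural network with self-backpropagation (SBP-SNN): synthetic
data generation, preprocessing, spike encoding, the decoder itself,
electrode-subnetwork mining, fusion-model clustering, band biomarker
attribution, and directed spectral Granger connectivity.  Human-subject
experimentation, video stimulus handling, convolutional/recurrent
baselines and scalp topography rendering are out of scope; classical
machine-learning baselines are available only as thin wrappers over
scikit-learn.

## Synthetic study conditions

The generator (`sbpsnn.synth`) emulates the statistical structure of a
62-channel, 10–20-montage emotional-EEG study.  Each trial is
1/f^a background noise per channel (default exponent a = 1, RMS
10 µV), with:

- **Class effects**: additive band-limited oscillation (order-6
  Butterworth-filtered noise, steep skirts so the injected power stays
  inside the nominal band) on designated electrodes, scaled so the
  band's power is multiplied by the configured factor.  The default map elevates beta (12–30 Hz) power on the
  parietal row for the negative emotions (fear ×2.0, sad ×1.8) and
  modulates alpha on the frontal-central/temporal rows for happiness
  (×2.0), reflecting the band-specific markers the analysis is designed
  to recover.
- **Directed couplings**: lagged source-to-sink contributions with the
  given VAR coefficients (defaults: parietal P1→P2, P1→P5 and
  frontal-central FC2→FC1 at 0.35).
- **Blink artifacts**: stereotyped 300 ms biphasic pulses (80 µV at the
  prefrontal row, exponential spatial decay with a 40 mm constant) at a
  default 8/min, marked in the event list so cleaning can be verified
  against ground truth.

Defaults are 250 Hz sampling (1 kHz supported) and 20 s trials with a
500 ms pre-onset lead-in.  What the generator does *not* model: forward
source-to-scalp projection, non-stationary emotional intensity,
inter-subject variability beyond independent noise, and realistic
channel covariance.  Passing tests therefore demonstrate that the
algorithms recover planted structure of realistic strength — not
performance on real recordings.

**Desk-scale decoding tasks** (`sbpsnn.tasks`) freeze the conditions the
multi-seed experiments run at: binary fear-vs-neutral with a beta-power
×3 effect on P1+P2 among a 5-electrode parietal context, 32 trials per
class of 1.5 s at 128 Hz, stratified 75/25 train/test split, 60 training
epochs with batch 20 and a 40 Hz teaching rate.  The effect strength was
chosen so that the decoder *without* SBP already learns clearly above
chance (≈66 % held-out accuracy), leaving room to measure the SBP
direction; the sizes keep a 20-seed experiment within minutes on one
CPU.  The separable fixture used for the learning check plants a single
input neuron that fires (0.2 per step) only for one class over a 1 %
background.

## Preprocessing

Butterworth band-pass 0.5–48 Hz, order 4, applied forward–backward
(zero phase).  Infomax ICA (via MNE's `infomax` unmixing on
rank-truncated PCA-whitened data) with automatic rejection of components
whose absolute correlation with the Fp1/Fp2 composite exceeds 0.7; the
pipeline applies ICA after filtering and before common-average
re-referencing.  Baseline correction subtracts the 500 ms pre-onset
mean.  Time-frequency band power uses a complex Morlet CWT
(`cmor1.5-1.0`) on 40 log-spaced centre frequencies tiling 0.5–48 Hz,
averaged within the five canonical bands (delta 0.5–4, theta 4–8, alpha
8–12, beta 12–30, gamma 30–48 Hz) and within 100 ms frames.  Mains
interference is excluded by the 48 Hz band edge; no separate notch.
The gamma band abuts the low-pass edge, so its power is slightly
attenuated; this bias is noted, not corrected.

## Spike encoding and spatial grid

Threshold encoding is a cumulative temporal-contrast (sigma–delta)
code: a per-channel accumulator integrates the signed first difference
and emits an ON (OFF) spike when it crosses +θ (−θ), subtracting the
quantum and carrying any surplus to later steps (binary trains, at most
one spike per polarity per step).  θ defaults to 0.5 × the SD of the
first difference; the decoding tasks calibrate θ on the pooled trials so
between-trial amplitude differences survive as rate differences.  The
471-node spatial grid is a 10 mm lattice clipped to an ellipsoid (axes
46×55×43 mm) whose interior contains exactly 471 points; electrodes are
assigned their nearest node (scalp sites project onto the outer shell).

## The decoder

Architecture 100/200/{1, 4}, hidden E:I = 1:1 with the Dale constraint
re-imposed after every update, weight clipping at ±1 for the readout.
Forward simulation is clocked at the encoder's dt with forward-Euler
LIF dynamics (τ_m 20 ms, v_th 1, reset 0, refractory 2 ms) and
Tsodyks–Markram STP at both synapse layers.  STP runs in a
facilitation-dominant regime (U = 0.05, τ_f 200 ms, τ_d 300 ms): with
larger U the depression term makes steady-state synaptic drive nearly
rate-invariant and erases the rate-coded class signal; small U keeps
drive approximately linear in presynaptic rate.  Synaptic efficacies
enter the membrane as instantaneous kicks scaled by 1/U, so the first
release from rest delivers exactly the weight.

**Calibration.**  Encoded spike density varies by an order of magnitude
across sampling rates and datasets, so before training the model
(i) scales each hidden neuron's incoming weights so its steady-state
membrane level under a data sample is 1.3 × threshold, (ii) equalises
the total outgoing weight mass per input neuron (fan-out normalisation,
so later divergence in electrode weight mass is learned, not inherited),
and (iii) sets the output synaptic gain so mid-range readout weights
(0.05) put the output at 1.5 × threshold — the learnable readout range
then spans silence to strong firing.

**Teacher-driven plasticity.**  The teaching signal is a regular spike
train at the configured rate into the true-class output.  Per batch the
output-synapse update is (presynaptic STDP-trace mass) × (teaching −
realised spike count), batch-mean normalised — a rate-coded form of
teacher-paired potentiation and output-paired depression whose
expectation is the gradient direction of C on rates.  Time-locked
pair sampling was evaluated and rejected: its depression term samples
the covariance between a hidden neuron's trace and the output spikes,
which actively decorrelates the output from its strongest drivers and
provably cannot form a discriminative readout.  Updates use learning
rate 0.2 with a 1/(1 + epoch/max(10, epochs/3)) anneal, class-interleaved
batches, weight decay on the readout (default 0.02; 0.1 for the
broadband task whose readout is heavily over-parameterised relative to
36 training trials), and tail averaging of the weights over the final
third of epochs.

**SBP.**  The potentiating and depressing parts of each hidden neuron's
outgoing adjustment are mirrored onto its active incoming synapses with
proportions ρ_LTP = 0.9 and ρ_LTD = 0.6.  "Active" is graded by an
error-gated salience: per-trial outer products of input trace mass and
hidden rate, weighted by the trial's teaching error and centred within
each hidden neuron's afferents.  The centring matters: a uniform mirror
only rescales each hidden neuron's input gain, which homeostatic
threshold scaling cancels exactly, whereas the centred component
reshapes selectivity.  The mirrored step is RMS-normalised to 5 % of the
input-weight RMS per batch.  A boolean "any presynaptic spike this
batch" gating is available as `sbp_gating="boolean"`.

**Homeostasis** multiplies each hidden threshold by
(1 + γ (rate − target)/target), γ = 0.05 annealed with the learning
rate, bounded to [0.5, 2] × the initial threshold; target 20 Hz.

**Decision rule.**  Multi-class: arg-max output spike count, ties to the
lowest class index.  Binary (one output neuron): the count threshold is
calibrated as the midpoint of the class-mean training counts; the
uncalibrated fallback is half the nominal teaching count.  A fixed
nominal threshold proved degenerate under a regularised, partially
converged readout, whose absolute count level is not pinned to the
teaching rate.

## Mining, fusion, biomarkers, connectivity

**Mining** partitions the montage into seven subnetworks by longest
10–20 label prefix (Fp/AF, F, FC/FT, C/T, CP/TP, P, PO/O) and
iteratively eliminates the lowest-contributing electrode, retraining
from fresh initialisation each step; the early stop fires after three
consecutive steps below chance + 5 points.  Contribution defaults to
*occlusion*: silence one electrode's input streams at inference and
measure the drop in output-count class separation (clipped at zero,
normalised to percent).  Input-weight mass and drop-one retraining are
provided as alternative modes; weight mass is uninformative under the
centred SBP update, which is mass-neutral per hidden neuron.  Best
model = highest accuracy, ties broken by higher F1 then fewer
electrodes; simplest = final step.

**Fusion** clusters (accuracy, F1) points with a hand-rolled Lloyd
K-means (k = 2, standardised features, best of 10 restarts, objective
trace exposed), takes the higher-accuracy cluster per kind, pools the
member models' electrodes (order-preserving union) and trains a decoder
per fusion kind; BFM/SFM/BSM are reported side by side without asserting
an ordering.

**Biomarkers**: per-band decoding filters each trial to one canonical
band (order-4 Butterworth), re-encodes with pooled thresholds and runs
the standard decoder (weight decay 0.02 — the narrowband readout needs
less capacity control); per-band accuracy is the 2-fold cross-validated
mean (independent trainings per fold, every trial evaluated once), which
the band arg-max comparison needs because single small test splits are
dominated by evaluation noise.  EasyMKL builds one trace-normalised linear
kernel per band from standardised band-power features and solves the
margin problem over the product of class simplices with SLSQP
(regulariser λ = 0.2); kernel weights normalised to percent are the
band contributions, one-vs-rest averaged for multi-class.

**Connectivity**: pairwise Geweke spectral Granger causality from an
OLS-fitted bivariate VAR (default order 20; stability checked via the
companion spectral radius), evaluated at integer frequencies 1–48 Hz.
Directed networks keep band-averaged edges above the 95th percentile of
trial-shuffle surrogates (the source channel's trial assignment is
permuted, destroying coupling while preserving autostructure); a fixed
threshold mode exists.  The factor-analysis circle plots of the source
study are replaced by a Welch magnitude-squared coherence summary per
electrode pair and band — the full discriminative cross-spectral factor
analysis is a separate method and out of scope.

## Numerical choices and degenerate inputs

Filters are SOS, forward–backward.  Constant channels encode to
all-zero trains with a warning.  ICA failure (rank < 2) returns the
input unmodified with a flag.  K-means flags all-identical inputs as
degenerate.  VAR fits require 10 × order × channels samples.  GC values
are clipped at 0 (the log ratio of nested-model spectra).  All
randomness flows from explicit integer seeds through
`numpy.random.default_rng`; training, mining and the full pipeline are
bit-reproducible for a fixed configuration.

## Known limitations

The SBP benefit did not reproduce at desk scale: over 20 matched seeds
on the standard task the SBP-on and SBP-off arms are statistically
indistinguishable (difference under one accuracy point, well inside seed
noise).  The mechanism analysis is in the SBP section — uniform mirrors
reduce to gain changes that homeostasis cancels, and selective mirrors
are noise-limited at 48 training trials — so the ablation is reported as
a directional equivalence (the improvement direction is not
contradicted), not as a demonstrated gain.  With weaker planted effects
both arms sit at chance and no ablation is expressible at all.  The binary decision threshold
is calibrated on training counts and can misplace when training counts
are degenerate.  Band-power attribution near the 48 Hz edge
underestimates gamma.  Occlusion contributions are computed on the
training split and inherit its sampling noise.  The spectral GC is
pairwise, not fully conditional — indirect influences through a third
channel are not partialled out beyond the surrogate threshold.
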