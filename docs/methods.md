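# Methods

## Problem and approach

In motor-imagery brain-computer interfaces (MI-BCI), imagining a movement
modulates the power of sensorimotor rhythms (mu, 8–13 Hz) over specific scalp
sites — event-related desynchronization (ERD) and synchronization (ERS).
Decoding pipelines typically record from many electrodes, although a small,
subject-specific subset carries most of the class information. `ecaselect`
implements a learnable channel-selection method: a channel-attention (CA)
layer is placed in front of a deep CNN so that, while the network is trained
to classify four imagery classes, the layer learns a per-electrode gating
weight; averaging the gate over the training set yields an importance ranking
from which a subset of any size `N_c` is taken and the network retrained on
the reduced montage.

## Attention model

An efficient-channel-attention (ECA) module squeezes each channel of a
feature block `X ∈ R^{W×H×C}` to a scalar by global average pooling,

    y_c = mean over the W×H plane of channel c,

maps `y` through a small shared transform, and gates the channels with the
sigmoid of the result, `Y = w · X`. Two transforms are used:

* **Inter-layer ECA modules** (attention over CNN feature maps): a shared 1-D
  convolution over the pooled vector, `w = σ(Conv1d_k(y) + b)` with a single
  bias `b`, so the module has `k + 1` trainable scalars. The kernel size
  adapts to the channel dimension, `k = ψ(C)`, the odd integer nearest to
  `log2(C)/2 + 1/2`; when the value lands exactly between two odd integers
  (e.g. `C = 128`, value 4.0) the larger one is taken, which makes
  `ψ(32,64,128,256) = (3,3,5,5)` and the module sizes `(4,4,6,6)`. The
  convolution zero-pads `(k−1)/2` on each side so the output length is `C`.
* **The CA layer** (attention over EEG electrodes, placed before the first
  convolution): electrode interactions are not spatially local — contralateral
  couplings matter — so the shared local convolution is replaced by a full
  square linear map, `w_CA = σ(W_CA y + b)`, with `C² + C` parameters (506
  for `C = 22`) and no dimensionality reduction.

The attention is input-dependent: `w` is a function of each sample's pooled
descriptor. Where a single per-electrode weight is needed (ranking,
reporting), the package uses the *expected attention* — the elementwise mean
of per-sample attention vectors over a dataset. An alternative static
ordering by the row norms of `W_CA` is available behind
`extract_channel_weights(..., method="weight_norm")` as a diagnostic, but the
expected attention is the default and the documented behaviour. Note that on
EMA-standardized input the pooled descriptor is close to zero, so the learned
bias `b` carries most of the static between-electrode differentiation; the
expected attention captures both this and the input-dependent part.

## Network

`build_eca_deepnet` assembles the stack for a `C × T` input: CA layer →
temporal convolution (32 filters, kernel 10×1, shared across electrodes) →
spatial convolution (32 filters, 1×C, collapsing the electrode axis) →
batchnorm → ELU → maxpool 3×1 (stride 3) → ECA → dropout, followed by three
further conv–batchnorm–ELU–pool–ECA blocks with 64/128/256 filters (no
dropout after the fourth block), and a convolutional classifier whose kernel
spans the full remaining temporal extent (7 for the canonical 22×1,000
input), ending in log-softmax. For the canonical input the symbolic shape
trace is 991 → 330 → 321 → 107 → 98 → 32 → 23 → 7 along time.

Parameter-count conventions, fixed by the per-layer counts this architecture
is specified with: block convolutions carry **no** bias (320 = 32·10;
22,528 = 32·32·22; 20,480; 81,920; 327,680), the classifier carries bias
(7,172 = 4·256·7 + 4), batchnorm contributes 2 per feature map, the CA layer
`C² + C`, each ECA module `k + 1`. The declarative `NetworkSpec` and a direct
enumeration of the runtime arrays must agree; a test asserts this.

The network, its backpropagation and the AdamW/Adagrad/Adadelta optimizers
are implemented in NumPy (`_nn.py`): convolutions are cross-correlations
evaluated with `sliding_window_view` + `tensordot` so inner loops run in
BLAS, and every layer's analytic gradient is verified against central finite
differences in the test suite (relative error ≲ 1e-6). Everything is
deterministic given the seed; there is no GPU path.

Training defaults (modal values of the per-subject tuning tables, all
configurable): dropout 0.5, AdamW, learning rate 1e-3, batch 16, weight decay
1e-4, 200 epochs with early stopping on validation loss (patience 30), seed
20200220. Weight decay is decoupled (AdamW) and skipped on biases and
batchnorm parameters. Initialization is Glorot-uniform for convolution and CA
weights, zeros for biases — so the CA sigmoid starts near 0.5, well away from
saturation. Loss is the negative log-likelihood of the log-softmax head.
Accuracy is reported per crop by default; a per-trial majority vote is
optional (`vote_by_trial`).

## Preprocessing

The continuous-signal pipeline, in order: (1) zero-phase band-pass 1–40 Hz
(4th-order Butterworth run forward and backward; only the band is inherent to
the method, the realization is this package's choice); (2) per-channel
exponential-moving-average standardization with decay 0.999 — running mean
`m_t = λ m_{t−1} + (1−λ) x_t` (initialized at the first sample), running
variance analogously (initialized at 1), output `(x_t − m_t)/max(√v_t, 1e−4)`;
(3) sliding-window cropping: per cue event the segment −0.5 s → 4 s is
extracted and 4-s (1,000-sample) windows are placed at stride 62 samples,
giving 3 crops per trial and 864 balanced crops from a 288-trial session.
The stride is a choice: the session geometry fixes only the 125-sample slack
and the total of 3 crops/trial; 62 spreads the three placements evenly and is
exposed as a parameter. Crops never straddle trials, and train/test splits
are made by trial so crops of one trial never land on both sides.

## Channel selection loop

1. Train the full-montage network.
2. Average the CA layer's per-sample attention over the training crops.
3. Rank electrodes by descending weight (ties keep the lower original index).
4. Take the first `N_c` as the subset; restrict the data; rebuild the network
   for `N_c` electrodes (spatial kernel 1×N_c, CA layer `N_c² + N_c`) and
   retrain from scratch with the same seed. Masking without retraining is
   deliberately not the default — the before/after models are separate fits.

`ChannelSubset` records channels in ranking order (with provenance), but
`channel_sweep` restricts the data keeping the original montage order. This
makes the full-size sweep (`N_c = C`) bit-identical to a direct full-channel
run — a reproducibility property the test suite asserts exactly — whereas
ranking-order restriction would permute the input rows and change the seeded
initialization's meaning. The subset files preserve ranking order for
consumers who need it.

The statsmodels-style surface (`ChannelSelectionModel(...).fit()` →
`ChannelSelectionResults`) packages the loop: the results object carries the
trained network, mean weights with per-sample dispersion, the ranking, a
`summary()` table, `select(n_c)` and `sweep(sizes)`.

## Synthetic motor-imagery generator

The generator emulates the geometry of a standard four-class session — 22
electrodes (10-20 names shipped as `MONTAGE_22`), 250 Hz, 288 trials (72 per
class) spanning −0.5 → 4 s around the cue — with known ground truth so the
whole loop is testable without recordings. Each channel carries:

* pink background noise, 1/f at 10 µV RMS, plus 1 µV RMS white sensor noise
  (typical resting-EEG-like spectra);
* a mu rhythm: white noise band-passed to 8–13 Hz at 15 µV RMS baseline —
  narrowband noise rather than a sinusoid, to avoid trivially separable phase
  cues.

During a trial of class `k` the rhythm amplitude on that class's informative
channels is multiplied by `1 − erd_depth` from cue onset to trial end, so
band power there drops by `(1 − erd_depth)²`; the default depth 0.5 is a
strong-but-realistic ERD. The default class→channel map mimics contralateral
motor cortex (left hand → C4, right hand → C3, feet → Cz, tongue → CPz).
Trials are separated by 2 s rest gaps so the slow EMA statistics cannot bleed
class information across trials. The rhythm RMS (15 µV) is set so the mu band
is rhythm-dominated: the measured own-class/other-class band-power ratio then
tracks `(1 − d)²` to within the in-band pink floor (a tested ±30% contract).

What the generator does *not* emulate: volume conduction (no forward model,
channels are independent), artifacts (EOG/EMG), non-stationarity across a
session, and realistic between-class overlap. Passing tests therefore
demonstrate that the machinery recovers planted band-power structure, not
that any particular accuracy is attainable on real EEG.

## Problem sizes used by the test suite

Training a CNN of this depth on full-size sessions is a multi-hour job, so
behavioural tests run the identical code paths at reduced scale, a deliberate
package choice:

* **Small harness** (most training tests): 8 channels, 125 Hz, 2.5-s trials,
  10 trials/class, filters (8,8,16,16), temporal kernel 6, pool 2 — seconds
  per fit.
* **Planted-recovery benchmark**: 22 channels, 125 Hz, 4.5-s trials, 16
  trials/class, `erd_depth` 0.9 (high SNR by construction), rhythm 20 µV,
  filters (16,16,32,32), 18 epochs, AdamW 1e-3 — ten seeded runs; the
  attention top-8 must contain ≥ 3 of the 4 planted electrodes in ≥ 8 runs.
  Hypergeometric chance for a single run is ≈ 0.12, so the criterion is far
  outside luck.
* The canonical 22×1,000 geometry is exercised symbolically (shape/parameter
  table) and once end-to-end through preprocessing (288 trials → 864 crops).

## Numerical choices and edge cases

* Adaptive kernel ties round to the larger odd integer (see above); `ψ ≥ 1`
  always; non-positive channel dimensions raise.
* Band-pass measurement on sinusoids is taken in steady state — `filtfilt`
  edge transients are excluded — matching the filter's frequency response.
* Maxpool drops the trailing remainder (`floor(L/3)`); batchnorm uses eps
  1e-5, momentum 0.1, affine, running stats for evaluation.
* Too-short inputs fail at build time with the offending layer named, not at
  run time mid-forward.
* Ranking ties (exactly equal weights) keep the original montage order,
  making the ranking deterministic.
* A non-finite training loss raises immediately, naming the epoch.

## Known limitations

* CPU-only NumPy training: full-size sessions train orders of magnitude
  slower than a GPU implementation; the package is sized for method study,
  desk-scale validation and small sessions, not large-scale benchmarking.
* The expected-attention weight definition is one of several reasonable
  readings of "weights collected after training"; the `weight_norm` flag
  exists to probe the alternative.
* Reported sweep prediction times are wall-clock and hardware-dependent;
  they are excluded from assertions.
* GDF/EDF ingestion delegates to `mne` and assumes cue annotations; montages
  other than the shipped 22-name list must be supplied by the caller.
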