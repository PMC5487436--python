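# Methods

This note documents the models implemented in `evsnn`, the parameter
choices that matter, the synthetic data used to exercise them, and the
numerical decisions a user should know about.

## Neuron model

Every spiking unit is an event-driven leaky integrate-and-fire neuron with
linear leakage and delta-Dirac (instantaneous) synapses. State is touched
only when an event arrives: the leak accrued since the last update is
applied first, then the synaptic weight (input sign × weight sign sets the
direction). Between events the membrane V decays toward the resting level
at a constant rate,

    dV/dt = −(TH₊ − rest)/TL₊   if V > rest
    dV/dt = +(rest − TH₋)/TL₋   if V < rest

clamping at rest (it never overshoots). Crossing TH₊ (inclusive — a weight
equal to the threshold fires) emits a +1 spike and resets to rest;
crossing TH₋ resets as well, emitting a −1 spike only in the signed
configuration. TL is therefore the time for a membrane at threshold to
fade to rest, in µs; TL = 0 disables leakage.

Two standard configurations:

* **Convolution layer (C1):** symmetric thresholds (TH₋ = −TH₊), negative
  crossing resets *silently* (no −1 event is communicated).
* **Classifier (FC):** positive-only neurons with TH₋ set to the numerical
  precision limit −2³¹. This value is treated as a real (silent) reset
  bound, not as "no negative threshold": it is what keeps wrong-class
  membranes from sinking without limit during a continuous pass. Its
  below-rest leak rate mirrors the above-rest magnitude
  (TH₊ − rest)/TL₋ — the sentinel exists to disable negative spiking, not
  to set an astronomically steep leak slope.

An optional refractory period (default 0 µs — no published value exists
for the runs being reproduced) discards inputs arriving within the window
after a spike; leak continues to act during refractoriness.

**Numerical representation.** Membranes are float64 while all weights and
thresholds are integers. Since integers below 2⁵³ are exact in float64,
every event update is exact integer arithmetic; only the leak introduces
sub-unit fractional parts, and it then tracks the continuous linear-decay
trajectory instead of a per-interval floor. This is what makes the
event-driven path agree with a 1 µs clock-driven Euler integrator to
within one membrane unit at every event (a property the test suite checks
over 10⁴ random streams at thresholds 10⁷–8×10⁸ and leaks 10⁴–10⁶ µs):
with floor-to-integer leak the rounding bias accumulates across events and
can exceed any fixed band.

## Network and execution

Topology: input (n×n) → C1, 18 feature maps of (n−k+1)² neurons sharing
one k×k Gabor kernel each → S1, 2×2 subsampling → Flatten → fully
connected spiking classifier (one positive-only neuron per class).
Convolution is *valid* (no padding) and applied as correlation: the output
neuron at (ox, oy) covers input rows/columns ox…ox+k−1, reached through
tap kernel[y−oy, x−ox]. The printed feature-map sizes this geometry must
reproduce (22×22 from 28/7, 28×28 from 34/7, 2,178 Flatten neurons for
28×28) all follow from n−k+1; a configuration whose pre-pool side is not
divisible by the pooling factor is rejected at load time rather than
silently cropped.

Subsampling defaults to pure address decimation (every event forwarded at
(⌊x/2⌋, ⌊y/2⌋)), which conserves event count; an accumulate mode (one
output per m net inputs per pooled address) is available since some prior
event-driven ConvNets pool by summation. Flatten is the bijection
index = map·side² + y·side + x.

Kernels are generated from the standard Gabor form (the printed source
formula is typographically garbled; the standard form reproduces the
expected 9-orientation × 2-phase bank of oriented edge detectors) and
quantized to integers at a configurable scale (default 10⁶, worst-case tap
error 0.5/scale; whether and how the original runs quantized C1 kernels is
not recorded anywhere, so the scale is exposed as a parameter).

Two execution paths produce identical event logs (asserted in tests):

* a **scheduler** in the style of event-driven AER simulators — a netlist
  of modules connected by nodes; the kernel repeatedly dispatches the
  globally earliest unprocessed event (ties broken by node registration
  order, then FIFO), records the (pre-request, request, acknowledge)
  handshake triple, and queues module outputs at now + module delay;
* a **feed-forward pipeline** that cascades each input event depth-first
  through the layer chain — equivalent for a zero-delay feed-forward
  netlist — with a numba-compiled kernel for large runs (the compiled and
  per-event reference paths are compared event-for-event in the suite).

## Encoders

* **Poisson:** per-pixel expected counts proportional to intensity,
  jointly scaled so the population emits exactly `total_spikes` events
  (default 1,000) over the stimulus duration (default 255 µs), with no
  pixel expecting more than `max_spikes_per_pixel` (default 15; excess is
  redistributed by water-filling). The budget is allocated by a single
  multinomial draw — independent Poisson draws rescaled afterwards cannot
  hit the total exactly — and timestamps are uniform in [0, duration).
  Whether the original timestamps were uniform draws or homogeneous-
  process inter-arrivals is indistinguishable downstream once the total is
  fixed.
* **Intensity-to-latency:** one spike per *nonzero* pixel at
  t = round((1 − I/255)·duration). The zero-intensity limit (a spike at
  the full duration) is read as the limiting value of the delay map, not
  as an instruction to emit background spikes: the reported per-sample
  input activity of the original latency runs (~151 events against 784
  pixels) shows background pixels were silent in practice.

Both encoders are deterministic given (image, config, seed).

## Training and mapping

Per sample, Flatten spike counts are normalized by their maximum into an
analog frame in [0,1]^h (an all-empty record maps to the zero vector — it
carries no information either way). A bias-free softmax regression is
trained by mini-batch SGD from a **zero initialization** (the problem is
convex, so the deterministic start costs nothing), with uniform seeded
reshuffling each epoch, fixed η = 0.1, and an epoch budget set per
experiment. The analytic gradient (1/|D|) Σ (Y(xᵢ) − onehot(Lᵢ)) xᵢᵀ is
release-gated by a central-difference check at 1e−6.

Mapping to spikes: W_int = round(K·W) with K = TH_FC = 10⁷ by default.
Because argmax is scale-invariant, prediction survives the mapping
whenever logit gaps exceed the rounding bound h·0.5/K — monitored via the
recorded worst-case rounding error.

**Spiking readout:** predicted class = output neuron with the most spikes
in the sample window; ties go to the earliest first spike; a sample with
no output spikes is scored incorrect and counted in a separate
"no-decision" tally. (No readout rule is recorded for the original runs;
spike count is the natural dual of the histogram objective.)

## Presentation regimes

**SBS** (sample by sample): zero leakage, all state explicitly reset
between samples. **OP** (one pass): all samples concatenated into one
stream, leakage active, histograms and readout computed per annotated
sample window, training and testing under the same leak settings. With
leakage disabled and explicit boundary resets the two regimes coincide
event-for-event (a test asserts this).

OP needs a long enough inter-sample gap for every membrane to fade to
rest. With linear leakage the fade time is proportional to the excursion:
classifier membranes can reach the −2³¹ bound, and at the default FC leak
rate (10⁷/12,000 µs ≈ 833 units/µs) full recovery takes up to ~2.6 s, so
the default OP gap is 3 s of simulated time. Gaps are free to simulate —
the event-driven state is advanced lazily — but this is a real physical
cost of the linear-leak model that a deployment would have to respect.

## Synthetic fixtures and study conditions

The fixtures stand in for handwritten-digit and event-camera data sets at
desk scale: 4 classes, 125 samples per class (400 train / 100 test, 80/20
split), 28×28 geometry, 200 training epochs, batch size 100.

* **Oriented-bar images:** anti-aliased bars (Gaussian transverse profile,
  width 1.4 px, length 0.75·28) at orientations {0°, 40°, 80°, 120°} —
  a subset of the Gabor bank's angles so each class has a matching
  feature map — with ±2 px center jitter, ±4° angle jitter, and additive
  Gaussian noise (σ = 10 intensity units). A quadrature-pair Gabor energy
  check confirms each class mean peaks at its own orientation.
* **DVS-like streams:** the same bar sweeping along its normal at
  400 px/s for 20 ms; frames rendered every 1 ms are differenced and each
  pixel emits one ON/OFF event per contrast-threshold multiple (threshold
  25 intensity units) with the fractional remainder rounded
  stochastically — the per-pixel threshold jitter of a real sensor — so
  the expected event count is proportional to the distance travelled
  (≈3,400 events/sample). Uniform background noise arrives at 1 kHz over
  the array with random polarity. The emulation reproduces edge-locked
  events, polarity symmetry and noise, but not sensor-level effects
  (per-pixel refractory periods, hot pixels, log-intensity response), so
  passing results bound fidelity of the *conversion*, not performance on
  real recordings.

For these fixtures the C1 threshold is 5×10⁶ at kernel scale 10⁶: an
aligned bar under latency encoding (one spike per pixel) drives a
matching-orientation neuron by roughly 10–13 kernel units ≈ 10⁷, so
aligned neurons cross threshold on a single pass while off-orientation
drive stays below — the same coarse, training-data-only adjustment the
original experiments describe for their per-dataset thresholds. Leak
magnitudes for OP (TL = 12,000 µs for both C1 and FC) follow the values
tabulated for the synthetic-image runs.

## Known limitations

* The synthetic task is much easier than handwritten digits: frame
  accuracies sit at 100%, so the classifier-loss bound is exercised near
  the zero-loss regime rather than at the 97–98% accuracy level of the
  real data sets.
* Only the single-convolution-layer topology is provided; the method
  itself ("retrain the output layer on spike histograms") applies to any
  feature extractor, and `SoftmaxClassifier` accepts frames from any
  source.
* Real-data adapters (N-MNIST binary, jAER DAT2.0) are readers only, with
  the bit layouts documented in `evsnn/aer.py`; no downloads are bundled.
* Event-camera OFF events enter the network as −1 spikes by default (the
  neuron model is signed); a `--rectify` option maps all polarities to +1,
  since which convention the original runs used is not recorded.
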