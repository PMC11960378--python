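# Methods

This note records the scientific and numerical choices behind swdnet: what is
modeled, which parameters matter, what the synthetic data does and does not
emulate, and where the design was genuinely open.

## Problem and pipeline

Typical absence seizures appear on scalp EEG as generalized ~3 Hz
spike-and-slow-wave discharges (SWDs), largest over frontal/central
electrodes, against a low-amplitude noisy background contaminated by blinks,
eye movement, muscle (EMG) and cardiac (ECG) artifact. The detector labels
every 2.56 s frame of a recording with a seizure probability and decodes the
frame sequence into seizure intervals. Stages, in run order: channel
selection → resampling → band-pass filtering → STFT + raw feature assembly →
per-record normalization → 64-frame example framing → network → event
decoding → event-overlap scoring.

## Channels and resampling

Only the 19 common 10–20 channels are used, in the fixed order fp1, fp2, f3,
f4, c3, c4, p3, p4, o1, o2, f7, f8, t3, t4, t5, t6, fz, cz, pz. Modern
temporal names (T7/T8/P7/P8) are folded onto the legacy ones (T3/T4/T5/T6)
because clinical files mix both conventions; a raw label resolving twice is a
hard error — silent montage mistakes are worse than a refusal. Signals are
resampled to 100 Hz by anti-aliased polyphase filtering (`scipy`'s
`resample_poly`); annotations are in seconds and unaffected.

## Band-pass filter

An order-12 Butterworth band-pass, half-power edges 0.16 and 35 Hz. "Order
12" is read as the total band-pass order (6 pole pairs per edge) — the usual
ambiguity for band-pass designs is resolved this way so the design has 12
poles. The filter is realized in cascaded second-order sections (stability
asserted against each section's pole moduli) and applied zero-phase
(forward–backward) by default so detected event boundaries are not delayed by
group delay; zero-phase application squares the magnitude response, i.e.
roughly 37 dB rejection at 50 Hz at fs 500 where a single pass gives ~19 dB.

A practical caveat measured during development: the 0.16 Hz low cut has an
impulse response lasting tens of seconds, so even with long reflection
padding the first/last ~15 s of a filtered record carry in-band transients.
Filter tests therefore measure steady-state response in the central third of
a 60 s probe, and event timing near record edges is correspondingly less
reliable on real data too.

## Features

Per channel and 2.56 s window (256 samples at 100 Hz, hop 128 = 50% overlap,
Hann taper — the taper is a free choice, as is the overlap): 128
log-magnitude spectrogram values log(1+|STFT|) of bins 0–127 (0–49.6 Hz)
concatenated with the same raw window decimated by 2 to 128 samples, giving
the 256-wide combined feature. A one-sided 256-point spectrum alone has 129
bins, so an explicit 128+128 split is forced; both halves cover the
frequencies and morphology a reader of clinical EEG actually uses (a 3 Hz SWD
peaks near bin 8).

Normalization is per record: the raw half is z-scored per channel; the
spectrogram half is z-scored with the record's global log-magnitude mean and
standard deviation. The mean subtraction matters: a device-gain change shifts
log magnitudes by an additive constant, which division by the standard
deviation alone would leave in place. Exact gain invariance holds for the raw
half; for the spectrogram half it holds only asymptotically, because
log(1+x) is nonlinear near zero — near-empty bins shift under a gain change.
Constant (degenerate) channels normalize to zeros and are logged rather than
raising.

Frames whose window lies at least 50% inside a reference seizure are labeled
positive. Examples are non-overlapping blocks of 64 frames; a trailing
partial block is zero-padded with padded frames masked out of loss and
metrics.

## Architectures

`resnet_bigru`: four residual blocks with channel plan 19→32→64→128→64. Each
block: conv3×3 → batch-norm → ReLU → conv3×3 → batch-norm on the main path, a
1×1 convolution on the identity path, elementwise Add then ReLU, then (1,2)
max-pooling — pooling halves only the feature axis, so the 64-frame sequence
survives to the output (shapes 64×256 → 64×128 → 64×64 → 64×32 → 64×16). The
encoder output (64, 16, 64) is flattened per frame to width 1024 and passed
through two bidirectional GRU layers (128 units per direction,
sequence-returning) and two per-frame dense layers to one probability per
frame.

Bias and gate conventions are pinned by the published per-layer counts:
3×3 convolutions are bias-free (batch norm absorbs the offset; 5472 = 9·19·32),
1×1 projections carry a bias (640 = 19·32 + 32), and the GRU uses the
dual-bias ("reset-after") gate form — reset gate applied after the recurrent
matrix product, two bias vectors per gate — which uniquely yields
886 272 = 2·3·(1024·128 + 128² + 2·128) for the first bidirectional layer.
These counts are asserted at construction: a drifting build fails loudly.
The published table also prints a handful of rows that are arithmetically
inconsistent under any standard formulation (a second bidirectional layer at
18 144 parameters, time-distributed rows at 16 512 and 1 296, an RNN input of
64×16×164); those rows are not reproduced and not asserted — the built layers
use the self-consistent values (296 448, 32 896, 129).

Comparison variants: `cnn_only` (the same conv stack without shortcuts, then
per-frame dense layers — no recurrence), `gru_only` (raw per-frame features
straight into the recurrent head), `cnn_gru` (shortcut-free conv stack +
recurrent head). All accept (64, 256, 19) and emit (64, 1); the sequence axis
is never shortened anywhere.

The layers are implemented on numpy (im2col convolutions, BPTT for the GRU)
with hand-derived gradients, each verified against central finite differences
in float64. Parameters are float32; batch statistics use running
mean/variance with momentum 0.9 at evaluation time.

## Training

Focal binary cross-entropy, the standard (α, γ) form with α = 0.25, γ = 2
(defaults of the method's literature; the γ factor suppresses the abundant
easy background frames that otherwise dominate under ~1% seizure prevalence).
Optimizer: Adam at 1e-3 (the "adaptive learning rate" family), L2 1e-4 on
convolution and dense weights only, dropout 0.3 after each recurrent layer
and the first dense layer. Masked frames contribute nothing to loss or
metrics. The kept checkpoint is the epoch with the best validation frame-F1
("best model" selection needs a metric; frame-F1 is the natural one for a
frame labeler under imbalance). Optional early stopping halts after a
configurable number of epochs without validation improvement. With a fixed
seed, runs are bit-reproducible in single-threaded BLAS.

## Event decoding and scoring

Frames ≥ 0.5 probability form maximal runs; a run spans first-frame window
start to last-frame window end; runs closer than 1 s merge; intervals shorter
than 1 s are dropped (decoding thresholds are free parameters echoed in every
report). Matching is greedy one-to-one in time order: a true event is
detected iff an unmatched prediction overlaps it by **more than 2 s** —
overlap is read as a duration, since it is given in seconds. True negatives
need a discretization (event lists define no negative count): background time
is tiled into 10 s windows and a window free of any prediction counts as TN.
TPR, TNR, PPV, NPV and F1 = 2·TPR·PPV/(TPR+PPV) follow; any zero denominator
is flagged undefined rather than raising or silently becoming 0. Frame-level
F1 is reported alongside; event-level metrics are the headline surface.

## Synthetic EEG

The simulator is phenomenological, not biophysical. Background: 1/f-shaped
Gaussian noise (15 µV sd per channel) plus an amplitude-modulated 9 Hz alpha
rhythm concentrated posteriorly. SWD bursts: a sharp positive Gaussian spike
(~70 ms) followed by a slow half-sine (~260 ms), repeated at 3 Hz,
synchronous across channels, ×1.5 on frontal/central channels, 120 µV peak,
cosine on/off ramps. Artifacts: large ~0.3 s frontal blinks, 20–80 Hz
band-limited EMG bursts on one temporal chain, and a faint periodic
QRS-like trace. Default seizure load is 1.08% of record time (the clinical
corpus imbalance); a balanced preset (20%) exists for CPU-scale training
studies. Event durations are drawn from 4–15 s until the target seizure time
is met (the last draw clipped toward the remainder, so realized totals sit
well inside ±20% of the target), and events are placed uniformly with ≥5 s
separation; an infeasible load/duration combination is a configuration error.
All randomness flows from one seed; records are independent streams of it.

What passing tests therefore show: the pipeline, features, network, training
loop and scoring are internally correct and can learn high-SNR 3 Hz bursts.
What they do not show: performance on real patients — real SWDs vary in
morphology and frequency within and across subjects, artifacts correlate
with seizures (eyelid flutter), electrode quality varies, and the simulator's
amplitudes and topography are plausible rather than fitted. Clinical claims
require clinical data.

## Study sizes and numerical choices

The end-to-end study trains on 20 simulated records × 120 s (balanced
preset, 15 train / 5 validation records, batch 8, ≤15 epochs with patience-3
early stopping) — sized so a laptop-class CPU completes it in minutes while
still exercising every architectural component at full input shape
(64 × 256 × 19). Probabilities are clipped to [1e-7, 1−1e-7] inside the loss;
EDF output quantizes to 16 bits with the physical range round-tripped through
its ASCII header field so writer and reader use the identical scale; the
resampling ratio is taken as a rational approximation with denominator ≤1000.

## Known limitations

- No re-referencing, artifact removal (ICA), or montage reconstruction.
- EDF writing is plain EDF + sidecar CSV annotations; EDF+ annotation
  channels are read but not written.
- Only typical absence (3 Hz SWD) morphology is simulated — no atypical,
  myoclonic or eyelid variants.
- The GRU backward pass is a Python loop over 64 time steps; fine at this
  scale, not tuned for long sequences.
- Zero-phase filtering makes detection non-causal; a forward-only mode
  exists but shifts event boundaries by the group delay.
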