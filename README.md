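# swdnet

Detection of typical absence seizures — generalized ~3 Hz spike-and-slow-wave
discharges (SWDs) — in multichannel scalp EEG, as a per-frame sequence-labeling
problem solved by a residual CNN encoder feeding a bidirectional GRU head.

The package is aimed at people building or evaluating automated seizure-time
annotation for clinical EEG review: it covers the whole path from an EDF file
to scored seizure intervals, and ships a synthetic-EEG simulator so every stage
is testable without patient data.

## The method

A recording is reduced to the 19 standard 10–20 channels
(fp1 … pz, legacy temporal names), downsampled to 100 Hz, and band-pass
filtered with an order-12 Butterworth design (0.16–35 Hz, zero-phase) that
removes drift and 50 Hz mains interference. Each channel is cut into 2.56 s
windows (256 samples, 50% overlap) and every window becomes a 256-wide feature
vector: 128 log-magnitude STFT bins

$$\mathrm{STFT}(f,t) = \sum_{\tau} x(\tau)\, h(\tau - t\cdot\mathrm{hop})\, e^{-i 2\pi f \tau / N}$$

concatenated with the same window's raw signal decimated to 128 samples, both
z-scored per record. Blocks of 64 consecutive frames form the network input
tensor `64 × 256 × 19`.

The flagship `resnet_bigru` network is a four-block residual CNN
(channel plan 19→32→64→128→64; each block is conv3×3–BN–ReLU–conv3×3–BN with a
1×1 projection shortcut, Add+ReLU, then (1,2) max-pooling so only the feature
axis shrinks: 256→128→64→32→16) followed by two bidirectional GRU layers
(128 units per direction, dual-bias gate form) and per-frame dense layers,
emitting one seizure probability per 2.56 s frame. Three comparison
architectures (`cnn_only`, `gru_only`, `cnn_gru`) share the same input/output
contract. Training uses focal binary cross-entropy
(α = 0.25, γ = 2) against the severe class imbalance (seizure time ≈ 1% of
record time), Adam, L2 and dropout, keeping the checkpoint with the best
validation frame-F1.

Frame probabilities are decoded into predicted intervals (threshold, merge,
minimum duration) and matched one-to-one against reference seizures: a true
event counts as detected when a prediction overlaps it by **more than 2 s**.
Reports carry TP/FP/TN/FN and TPR, TNR, PPV, NPV and F1 (harmonic mean of TPR
and PPV), with true negatives counted as clean 10 s background windows.

The neural layers (convolution, batch norm, bidirectional GRU, focal loss,
Adam) are implemented directly on numpy with hand-derived backpropagation,
verified by finite-difference gradient checks; the built network's per-layer
trainable parameter counts (e.g. 5 472 for the first 3×3 convolution, 886 272
for the first bidirectional layer) are asserted at construction time.

## Worked example

```python
from swdnet import SynthConfig, simulate_recording, preprocess_recording
from swdnet.evaluation import evaluate_events
from swdnet.eeg_io import EventList

cfg = SynthConfig.balanced(duration_s=120.0, seed=7)
rec, truth = simulate_recording(cfg)
print(f"record {rec.record_id}: {rec.n_channels} channels, "
      f"{rec.duration_s:.0f} s at {rec.fs:.0f} Hz")
print("planted events:", [(round(float(e.start_s), 1), round(float(e.end_s), 1))
                          for e in truth])

examples = preprocess_recording(rec)
print(f"{len(examples)} examples of shape {examples[0].tensor.shape}, "
      f"{sum(int(e.frame_labels[e.frame_mask].sum()) for e in examples)} seizure frames")

pred = EventList([(41.5, 56.0, "seizure"), (88.0, 92.0, "seizure")])
report = evaluate_events(pred, truth, rec.duration_s)
print(f"tp={report.tp} fp={report.fp} fn={report.fn} tn={report.tn}  "
      f"TPR={report.tpr:.3f} PPV={report.ppv:.3f} F1={report.f1:.3f}")
```

prints

```
record synth-00007-000: 19 channels, 120 s at 500 Hz
planted events: [(46.0, 59.4), (86.6, 95.7)]
2 examples of shape (64, 256, 19), 18 seizure frames
tp=2 fp=0 fn=0 tn=8  TPR=1.000 PPV=1.000 F1=1.000
```

The simulator planted two spike-wave bursts; preprocessing produced two
64-frame examples with 18 seizure-labeled frames; the hand-written predictions
overlap both true events by more than 2 s, so both count as true positives and
all metrics are 1. The eight TN windows are the 10 s background windows no
prediction touched.

The same pipeline is available from the shell:

```
swdnet simulate --out-dir corpus --n-records 5 --duration-s 120 \
                --seizure-fraction 0.2 --seed 1
swdnet preprocess --in-dir corpus --out-file features.h5
swdnet train --features features.h5 --variant resnet_bigru --epochs 10 \
             --out-dir run1
swdnet detect --model run1/model --recording corpus/synth-00001-000.edf \
              --out-file pred.csv
swdnet evaluate --pred pred.csv --truth corpus/synth-00001-000.events.csv \
                --record-dur-s 120 --out-file report.json
swdnet report --variant resnet_bigru       # per-layer parameter table
```

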