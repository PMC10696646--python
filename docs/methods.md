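# Methods

## Annotation vocabulary and grouping

Classification runs over a fixed, ordered 15-symbol vocabulary:
`N L R V A f F j a E J Q e S Z`. The first 14 are beat classes
(normal, bundle branch blocks, ventricular/atrial/junctional premature
and escape beats, fusions, unclassifiable); `Z` absorbs every non-beat
annotation (rhythm changes, waveform boundaries, quality and comment
markers). The grouping is a total function on characters, shipped as a
plain-text table (`ecgvision/data/symbol_groups.txt`): symbols the
WFDB annotation standard flags as beats but that fall outside the 14
named classes — paced beats (`/`), generic bundle branch block (`B`),
supraventricular escape (`n`), R-on-T (`r`), learning-phase beats
(`?`) — map to `Q`, the catch-all unclassifiable-beat class; unknown
symbols are treated as non-beat. The mapping is idempotent, and the
index of a symbol in the vocabulary is the integer class label used
throughout.

## Record I/O

`ecg_io` contains a self-contained reader/writer for the WFDB dialect:
plain-text headers, signal formats 16 (little-endian int16) and 212
(packed 12-bit pairs), and the MIT binary annotation format including
the SKIP long-interval and AUX/NUM/SUB/CHN pseudo-annotations (parsed,
then ignored). Amplitudes are converted to physical units via the
header gain/baseline; writing quantizes at a configurable gain
(default 200 ADU per unit), bounding round-trip error by half an LSB.
Multi-segment and variable-frequency records are out of scope. All
downstream analysis defaults to channel 0 (MLII in MIT-BIH ordering),
configurable per call.

## Windowing and image encoding

Windows are `n` samples centered on the annotation (`n` even;
defaults: 180 for the proposed network, 128 for the baseline); a
window that would cross a record boundary is discarded and the next
annotation considered. Skewed datasets re-cut each window at a
uniform integer offset in [−⌊n/4⌋, +⌊n/4⌋] (uniformity is the natural
choice absent any stated distribution and is chi-square-checked in the
tests); offsets that overrun the record are redrawn up to 10 times,
then fall back to 0.

The encoder lights, per column `c`, row `r = ⌊(w_c − min)/d · h⌋`,
`d = max − min`. Numerical details:

- **Clamping.** The formula yields `r = h` exactly at `w_c = max`; rows
  are clamped to `[0, h−1]`, and out-of-range samples are clamped to
  the limits first, preserving the one-lit-pixel-per-column invariant
  for any input.
- **Offset by the minimum.** `(w_c − min)/d` rather than `w_c/d`, so
  ranges with nonzero minima behave identically to the zero-based
  worked example.
- **Limits are configuration, not per-window statistics** — by default
  the pooled min/max of the analyzed channel over the input records.
  Per-window normalization would erase amplitude differences between
  beats, which are exactly what distinguishes e.g. ventricular
  complexes.
- **Orientation.** Row 0 is the minimum-amplitude row; images are
  upside-down relative to plotting convention and deliberately kept
  so (the orientation only has to be consistent).

`image_to_signal` decodes each column to its bin midpoint
(`min + (r + 0.5)·d/h`), giving a per-sample reconstruction error of
at most `d/h`; it exists for round-trip diagnostics, not for
processing.

Datasets pool windows from all input records, shuffle once with the
given seed and split 90%/10% train/test. No class balancing is
performed.

## Classifiers

Both networks are built on a small numpy layer engine written for this
package (`ecgvision.nn`): same-padded stride-1 convolutions via
im2col + BLAS matmul, 2×2/stride-2 valid max pooling (trailing odd
rows/columns dropped, e.g. 45 → 22), batch normalization (momentum
0.9, eps 1e-5), dense layers, ReLU, fused softmax cross-entropy, and
Adam. Every backward pass is verified against central-difference
numerical gradients in the test suite. Because everything is plain
numpy, a fixed seed makes weight initialization, shuffling and hence
the entire training trajectory bit-reproducible — there is no backend
nondeterminism to document away.

Architectures (15-way softmax output):

- **proposed**, input 180×64×1: Conv(8, 6×6) → pool → Conv(16, 5×5) →
  pool → Conv(32, 4×4) → pool → flatten (5,632) → Dense 512 → 256 →
  128 → 15. 3,061,991 parameters.
- **baseline**, input 128×128×1: three blocks of
  [Conv(k, 3×3) → BN → Conv(k, 3×3) → BN → pool] for k = 8, 16, 32,
  then flatten (8,192) → Dense 512 → BN → Dense 15. The printed
  source architecture lists a max-pooling layer after the dense head;
  pooling is undefined on a flat vector, so it is represented as an
  explicit no-op layer and flagged as such.

Choices left open by the source description, fixed here as defaults
and exposed as configuration: pool geometry 2×2 stride 2; "same"
convolution padding (required for three pool blocks to fit 180×64);
Adam at learning rate 1e-3 with categorical cross-entropy (the
standard pairing for this architecture family); batch size 512; He
initialization; no class weighting. Pixel values are scaled to [0, 1]
before the network. `epochs=0` is an explicit no-op returning the
untrained model.

The statsmodels-style surface — `BeatClassifier(train, test,
architecture).fit(...)` returning a `TrainingResults` with `history`,
`predict`, `evaluate` and `summary()` — wraps thin functional
primitives (`build_proposed`, `build_baseline`, `train`, `predict`)
that remain public.

## Metrics

From the 15×15 confusion matrix (rows = truth): accuracy =
trace/total; per-class one-vs-rest precision TP/(TP+FP), sensitivity
TP/(TP+FN), specificity TN/(TN+FP), macro-averaged over classes
present in the true labels. Zero-denominator classes are skipped, not
scored zero — a small test split should not be penalized for classes
it does not contain. Micro averaging is a switch. The averaging
convention for the published multi-class figures is not stated
anywhere authoritative; macro is the default here precisely because
both are implemented and reported explicitly.

## Streaming workflow

The simulator pushes one sample every `factor × 1/fs` seconds into a
ring buffer of capacity `n`; a full buffer evicts its oldest sample.
The factor (default 0.9) shortens the period to offset scheduling
overhead that otherwise stretches a run ~10% past real time. The
detector loop: copy the buffer (it never reads the live buffer
mid-task), optionally run the center check, convert to an image,
classify, and log the span `[total_pushed − n, total_pushed)`, the
label, the confidence (max softmax probability), per-stage times and
the number of samples pushed — and therefore missed — during each
stage.

The center check locates the sample of maximum absolute deviation
from the window median and accepts iff its index is within ±⌊n/8⌋ of
the center (tolerance configurable; the locator is pluggable). Argmax
ties break to the lowest index, so a flat window is deterministically
rejected. Rejected windows restart the loop.

Virtual-time mode replaces wall-clock sleeps with a logical clock in
sample-period units: each stage declares its cost in periods and
exactly that many samples are pushed while it "runs", making
missed-sample accounting exact and the whole workflow deterministic —
this is the testing surface; wall-clock timings are reported but never
asserted. Two scheduling rules keep the loop well-defined: after
every iteration (accepted or rejected) the detector waits for at least
one fresh sample before re-copying, so zero-cost detectors still make
progress; and the loop ends once the simulator has pushed the last
sample, so a classification during which the stream runs dry honestly
reports fewer missed samples than its cost. A buffer-of-buffers
variant (snapshotting on every push) is deliberately not implemented:
it either accumulates the whole recording or degenerates into reading
the live buffer, and the plain copy-on-demand loop already bounds the
loss to a few samples per classification.

The per-beat CSV (`ID, Location, Classification, Confidence`) and the
JSON summary (mean stage times, mean samples removed per stage, beat
counts per class) mirror the published report layouts. Confidence is
summarized two ways, both labelled: the mean over beats, and the
unweighted mean of per-class mean confidences.

## Synthetic records

The generator emulates exactly what the pipeline consumes: a fixed
sampling frequency (default 360 Hz), one analyzed channel (optionally
a second, attenuated one), beat annotations at R-peak sample indices,
and ≥ 2 distinguishable morphologies. Beats are sums of Gaussian
bumps — preset `N`: P wave, narrow tall QRS (amplitude 1.0), T wave;
preset `V`: wide high-amplitude complex without a P wave and a
discordant T — placed at truncated-normal RR intervals (default
0.8 ± 0.05 s, floored at 0.25 s), plus white noise (sd 0.03) and
sinusoidal baseline wander (amplitude 0.1 at 0.33 Hz). Annotations
are placed at the argmax of each beat's clean rendering, before noise
is added, which is what makes the center-check tests exact. Records
are byte-identical under a fixed seed.

What this does **not** emulate: real P/QRS/T asymmetries, rhythm
dynamics (e.g. the irregularity of atrial fibrillation), inter-patient
morphology variability, electrode artifacts, or realistic class
imbalance. Passing tests therefore demonstrate that the pipeline's
mechanics — windowing, encoding, learning, streaming accounting — are
correct and that the classifier can learn genuinely separable
morphologies; they say nothing about accuracy on clinical recordings,
which requires real annotated data such as MIT-BIH.

## Problem sizes used in the checks

The learnability check trains the proposed network from scratch on a
240 s two-class synthetic record (~270 training / ~30 held-out
images) for 10 epochs at batch size 32 — batch 512, the production
default, exceeds a desk-scale training set, and small batches give
Adam enough steps to converge. Conversion-oracle agreement is checked
on 1,000 random (signal, limits, height) triples; skew uniformity on
10,000 draws (chi-square, α = 0.01); streaming exactness on a 10 s
record whose length makes the per-classification miss count uniform.

## Known limitations

- The numpy engine targets clarity and determinism, not throughput;
  training beyond a few thousand images per epoch is slow compared to
  a GPU framework.
- No denoising is applied to input signals; the encoder assumes the
  amplitude range is meaningful.
- The WFDB reader covers single-file, single-frequency records in
  formats 16/212 only.
- The center check is an amplitude heuristic, not an R-peak detector;
  it is pluggable for that reason.
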