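# Methods

## Signal model and preprocessing

A trial is a synchronous multichannel recording at `fs` = 1000 Hz: 5
surface-EMG channels over the shoulder girdle and 3 accelerometer axes,
with a per-sample label over 7 classes (6 shoulder movements + rest). EMG
channels are band-pass filtered to 30–450 Hz with a 4th-order Butterworth
design applied forward–backward (zero phase; effective order 8). The
"4th-order, zero-phase" phrasing is ambiguous between design order and
effective order; we design at order 4 and filter bidirectionally, the most
common reading, with the order exposed in `FilterSpec`. Edge transients are
controlled by reflect padding of about one filter length.

A 2–20 Hz band-pass for the ACC axes is implemented (`ACC_BAND`) but the
feature path leaves ACC unfiltered by default (`RunConfig.filter_acc`).
Any 2–20 Hz band-pass removes the DC gravity projection, yet that
quasi-static, posture-dependent component is precisely what makes the ACC
axes informative for held movements: with it removed, ACC retains only
transition dynamics. The switch lets users reproduce either convention.

Because EMG (mV) and ACC (g) live on different scales and the DTW local
cost is scale-sensitive, each channel is standardized by its global mean
and standard deviation pooled over a subject's trials before windowing.
The statistics are global per channel — never per window — so
between-window offsets (the gravity projection) survive. Computing the
statistics per LOTO training fold instead would change only a near-constant
affine scale per fold at the cost of re-extracting all features once per
fold; we compute them once per subject. Standardization can be disabled
(`normalize=False`).

Windows of WL ∈ {50, 100, 150} ms tile each trial from its start with
stride = WL by default (non-overlapping; the stride is configurable). The
window label is the majority per-sample label, ties broken by the centre
sample — deterministic and orientation-free. Windows may cross
rest/movement boundaries; boundary windows therefore carry mixed content,
which is the realistic streaming situation.

## Spatial features: pairwise banded DTW

Each window's channels are expanded into derivative orders 0/1/2 (raw,
first, second discrete difference; lengths l, l−1, l−2). Within each order,
the DTW distance is computed for every unordered channel pair: squared
local cost, the classic step pattern {(1,0),(0,1),(1,1)} (no stalling
steps), endpoints (1,1)→(l,l), and a Sakoe–Chiba band `|e−f| ≤ w·l`.
Accumulation is a plain sum along the optimal path — no square root and no
path-length normalization. Cross-order pairs are never formed: only
within-order pairing yields the documented dimensions 3·C(Nc,2) (84 for 8
channels, 30 for 5). Features are ordered as derivative-order blocks, and
within each block channel pairs (i, j), i < j, lexicographically.

The band fraction defaults to `w = 1.0` (unconstrained): no value is
prescribed by the study design, and at 50–150 samples per window the
unconstrained DP is cheap. The DP kernel is JIT-compiled with numba; the
dynamic program is verified in the test suite against an independent
brute-force oracle that enumerates every valid banded path explicitly.

## Temporal fusion: STW and A-STW

The per-window feature stream is fused by a recursive cell state `c` with
memory factor β ∈ [0, 1), default 0.75:

* STW: `f_t = DTW_t + β·c`, then `c ← f_t`.
* A-STW: `f_t = attention(DTW_t, DTW_{t−1}) + β·c`, then `c ← f_t`.

With constant input v the recursion converges to `v/(1−β)` = 4v at the
default β, i.e. a ≈4-window memory. The cell is reset to zero at every
trial boundary and is never carried across trials.

The attention step reshapes the flat feature vector (length 3P) into a
3 × P matrix whose rows are the derivative-order blocks; these rows act as
the attention tokens. With Q = current window, K = previous window, V = Q,
the output is `softmax(Q·Kᵀ/d_k)·V`, flattened back. Three conventions are
deliberate and exposed as configuration:

* the matrix layout (3 × P by derivative order) — the only reshape
  consistent with a non-degenerate `Q·Kᵀ` for flat vectors that preserves
  the output dimension;
* row-wise softmax, numerically stabilized by subtracting the row maximum;
* scaling by `1/d_k` with `d_k = P` by default (a `1/√d_k` switch exists).

For the first window of a trial the previous vector is taken to be the
current one (self-attention), keeping the operator defined at t = 1. The
cell state accumulates the *attended* features, not the raw `DTW_t`.
Because each attention output row is a convex combination of the current
rows, every output entry is bounded by the column-wise extremes of the
current features; an isolated spike window is blended across tokens rather
than passed through, which damps feature-space outliers relative to STW.

Sensor conditions: `emg` (5 channels → 30 features), `emg+acc` (8 channels
→ 84, including all cross-modal pairs), and the ablation `merged` (A-STW
run separately on EMG → 30 and ACC → 9, concatenated to 39 — no
cross-modal DTW pair is ever formed).

## Separability index

For classes j, k with sample means `m` and unbiased covariances `Σ`, the
pairwise distance is `½·√((m_j−m_k)ᵀ Σ⁻¹ (m_j−m_k))` with
`Σ = (Σ_j+Σ_k)/2`. Each class's *most conflicting* class is its argmin
over this distance (evaluated with the candidate-specific pooled
covariance; ties to the smaller index), and SI is the mean over classes of
the distance to it. Inversion is regularized by adding
`λ·trace(Σ)/dim` to the diagonal with λ = 1e−6: with 84 dimensions and
per-trial per-class sample counts in the tens, pooled covariances are
rank-deficient and the raw index is undefined. Absolute SI values on such
short trials are therefore ridge-dependent; comparisons between conditions
at equal dimension and sample size remain meaningful. SI is computed per
trial (per participant) and averaged by the pipeline.

## Classifiers and evaluation

LDA (scikit-learn, SVD solver; optional shrinkage via the lsqr solver),
kNN (k = 5, Euclidean — a common default, odd to avoid vote ties), and a
canonical extreme learning machine: 200 logistic hidden units, input
weights and biases uniform in [−1, 1] from a recorded seed, ridge-solved
(λ = 1e−3) output weights on one-hot targets, argmax decision. Further
classifiers can be registered in `CLASSIFIER_PLUGINS` without touching the
protocol; an autonomous-learning multi-model classifier is such a plugin
point and is not implemented here.

Evaluation is leave-one-trial-out within each subject: one fold per trial,
plain window-level accuracy per fold, arithmetic mean across folds, summed
7 × 7 confusion matrix. Fold training sets are checked to contain every
class present in the dataset. Condition comparisons use the two-sided
Wilcoxon rank-sum test (α = 0.05), exactly as an unpaired rank-sum (not
signed-rank); fully tied samples return p = 1 by convention.

## Synthetic data generator

The generator emulates the acquisition protocol — 8 trials per subject,
each a schedule rest → movement → rest → … over the 6 movements — and the
two statistical structures the method exploits:

* EMG: per class c and channel ch, amplitude `A[c, ch]` modulates 30–450 Hz
  band-limited Gaussian noise. On top of white sensor noise
  (`emg_noise = 0.5` of carrier scale, ≈6 dB SNR), a slow multiplicative
  gain drift (0.5–3 Hz band, `emg_drift = 0.6`) emulates force drift and
  physiological tremor. The drift's correlation time of a few hundred
  milliseconds is essential: it is what makes features estimated on 50 ms
  windows noisier than on 150 ms windows, as with real surface EMG. Purely
  white noise would be averaged away by the β-recursion and short windows
  would never degrade.
* ACC: per class, a constant gravity-projection offset `G[c, axis]`
  (magnitudes ≤ 1 g), a small postural wobble, a damped 3–18 Hz oscillation
  burst at each segment transition, and white sensor noise.

Movement and rest segments last 3 s each (held postures of a few seconds,
as in typical protocols; segments must be ≥ 450 ms, three windows at the
longest WL). Gain rows for neighbouring movements overlap partially —
shared synergists — so EMG-only classification is good but not trivial.
Subject heterogeneity is log-normal multiplicative jitter on A (σ = 0.10)
and additive jitter on G (σ = 0.03), fixed per subject. Everything is
deterministic given `(seed, subject, trial)`.

What the generator does **not** emulate: motor-unit physiology, electrode
shift and impedance changes, EMG spectral nonstationarity, crosstalk
between electrodes, ACC translation components during movement, or
between-session variability. Passing tests therefore demonstrate that the
pipeline behaves as designed on signals with the assumed structure
(class-dependent EMG amplitude patterns plus quasi-static ACC postures);
they do not certify accuracy levels on real recordings.

Default scale is one subject × 8 trials — the unit on which the LOTO
protocol and the per-participant SI operate; multi-subject runs are a
config switch (`n_subjects`).

One consequence of the temporal recursion worth noting: the cell state
encodes segment *context*, so two classes made generatively identical are
still partially separable in the fused features through what preceded
them; controls for generative indistinguishability are therefore evaluated
on the unfused spatial features.

## Numerical choices and degenerate inputs

* DTW band inclusion uses a 1e−9 tolerance on `|e−f| ≤ w·l`; the diagonal
  is always inside the band, so a valid path always exists, including w = 0.
* Softmax stabilization subtracts the row max before exponentiation.
* CSV round-trips are exact: doubles are written with `%.17g` and parsed
  with pandas' round-trip parser.
* Trials shorter than one window, singleton classes, band edges at or above
  Nyquist, label codes outside 1..7, and missing label columns raise typed
  errors (`astw.errors`).
* ELM output weights solve a ridge system; LDA's SVD solver tolerates
  rank-deficient pooled covariance.

## Known limitations

* Real-recording accuracies are not reproduced here; the public shoulder
  EMG dataset can be converted to the CSV trial layout and run through the
  same CLI, but no downloader is included.
* The attention conventions (reshape, softmax axis, 1/d_k scaling) are
  declared choices among several consistent readings of the architecture;
  all are configurable.
* SI absolute values on short high-dimensional trials depend on the
  regularization strength (see above).
* The cell state never resets within a trial, so features near segment
  boundaries blend adjacent classes; with β = 0.75 this bleed spans roughly
  four windows and is the dominant error source at long WLs.
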