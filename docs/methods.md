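# Methods

## Model

The classifier consumes fixed-length windows ("segments") cut from
band-pass-filtered EEG trials, each a `C × T` matrix with a binary label
inherited from its parent trial.

**Encoder.** Three banks of K = 9 one-dimensional convolution kernels with
lengths `S_r = round(0.5^r · fs)`, r = 1..3, are shared across channels.
Seconds-to-samples conversions round half away from zero. Convolution is
valid (no padding), stride 1. Each filtered series is squared,
average-pooled and log-compressed with a floor, `log(·+ε)`, giving log
band-power features — each kernel acts as a learned FIR filter and its
feature row is its power profile over time bins. Kernel attention scores
row k of scale r by `(z_k · q_r)/‖q_r‖` with one trainable `q_r` per scale
(shared across channels, mirroring the kernel sharing), softmaxes the K
scores, and scales the rows. The concatenated, flattened blocks give the
`C × SK` node features, `SK = Σ_r K·F_r`.

**Task-specific graphs.** Per connectivity measure, the class-l adjacency
is the elementwise mean of per-segment connectivity matrices over the
class-l *training* segments only. Correlation enters through its absolute
value (negative weights have no square-root degree), the diagonal is then
set to 1 (the usual self-loop convention — PLI's natural diagonal is 0 and
would otherwise erase each node's self-contribution), and the result is
symmetrically normalized. Phase measures band-pass the segment, take
analytic-signal phases, and discard 1 s at each edge to suppress filter and
transform transients; a segment must therefore exceed 3 s. The phase-lag
index uses `sign(sin Δϕ)`; the sign of a *wrapped* phase difference is not
well defined, and `sin` makes the index the standard odd-symmetric
statistic. Coherence uses Welch estimates (1 s Hann windows, 50 % overlap)
and collapses the spectrum to one number per pair by the unweighted mean
over in-band bins.

**Graph stage.** First-layer propagation is per class graph,
`Z_l = relu(Ã_l Z W_l)` with `W_l ∈ R^{SK×SK/2}`. The adjacency-attention
gate scores each ordered channel pair by a logistic of the concatenated
first-layer rows projected on a trainable vector per class; the two class
scores are summed, so the gate lies in (0, 2) and multiplies both
normalized adjacencies elementwise. The gated graphs feed a second,
class-shared layer `W_as ∈ R^{SK/2×SK/4}`. No re-normalization follows the
gating — renormalizing would cancel the learned magnitudes. `SK ≡ 0
(mod 4)` is validated at model build so the halvings are exact.

**Fusion.** Each measure's two branch outputs are concatenated, flattened
(`C·SK/2` values) and mapped by a per-measure MLP (hidden width 64) to a
class-score pair, which is softmaxed — the softmax is *within* the pair;
the pairs of all active measures are concatenated and a second MLP (hidden
width 16) produces the final logits. Loss is mean cross-entropy plus
`λ Σ θ²` over non-bias parameters, λ = 1e-4 by default.

## Training and evaluation

Optimization is adaptive-moment gradient descent (lr 1e-3, batch 32) on a
numpy reverse-mode autodiff core, in single precision. Nested
cross-validation is stratified by class and keyed on trial ids: 5 outer
folds give the test estimates; within each outer training set, 4 inner
folds drive early stopping (validation loss, absolute improvement
threshold `tol = 1e-3`, patience 5, best epoch restored) and model
selection (highest inner validation accuracy, ties to the lowest fold
index). The selected model is fine-tuned on the full outer training set
for a fixed number of epochs (default 5) with adjacencies rebuilt from
that set, then evaluated once on the held-out trials. Segment-level
ACC/Precision/Recall/F1 are primary; a trial-level majority vote is
reported alongside. One master seed drives fold shuffling, weight
initialization and batch order; rerunning with the same seed reproduces
the fold plan and metrics files byte for byte.

Per-segment connectivity matrices depend only on the segment, so the
cross-validation driver computes them once per dataset and averages the
relevant training rows per fold — numerically identical to per-fold
recomputation, and the held-out rows are never read.

### Initialization

Weights are Glorot-uniform, conv kernels `N(0, 1/√S_r)`, projection
vectors `N(0, 1/√SK)`, biases zero — except the **output layer of each
per-measure head, which is zero-initialized**. With a random output layer,
some seeds start with a large coherent (sample-independent) logit offset
in the softmaxed pair; adaptive-moment updates amplify exactly that
direction until the pair saturates, after which the softmax jacobian
vanishes and the whole branch stops learning. Zero-initializing the head
starts every branch at the softmax's maximal-gradient point with no
offset, and the fused model then trains reliably across seeds.

### Defaults and their rationale

| parameter | default | why |
| --- | --- | --- |
| window / overlap | 4 s / 2 s | reproduces the standard 29 windows per 60 s trial |
| preprocess band | 4–45 Hz | the usual broadband EEG analysis range |
| pool length/stride | round(fs/4) | non-overlapping quarter-second power bins |
| log floor ε | 1e-6 | keeps silent input finite |
| λ | 1e-4 | weak shrinkage; weights only |
| lr / batch | 1e-3 / 32 | stable convergence of the fused model |
| max epochs / patience / tol | 12 / 5 / 1e-3 | the bundled benchmark converges by epoch ~2; these caps keep a full 20-fit nested CV tractable on one desktop CPU core. Raise `max_epochs` (e.g. ≥100) for harder, real recordings |
| fine-tune epochs | 5 | short consolidation on train+validation |
| variants | all four | the fused model is the flagship configuration |

Ablation toggles (`use_cnn`, `use_gcn`, `use_kernel_attention`,
`use_adjacency_attention`) change the architecture exactly: disabling the
CNN feeds raw samples as node features (`SK = T`); disabling the GCN
flattens encoder output straight into the fusion MLP; disabling either
attention removes its parameters and leaves the backbone intact.

## Synthetic data

Each trial is independent 1/f noise per channel (spectrally shaped white
noise, `1/√f` amplitude), plus — for the channels in the trial's
class-specific coupled set — a shared 10 Hz carrier with a slow common
random-walk phase drift and per-channel phase offsets drawn once per
dataset. Within a coupled set the pairwise phase difference is constant, so
within-class PLV/coherence on planted edges is high and stable across
trials, which is precisely the stationarity that class-conditioned
adjacency averaging assumes. Amplitudes default to coupling a = 1, noise
b = 0.2 (a/b = 5, the strong-coupling regime); the standard benchmark is 16
channels, 40 trials per class, 10 s at 128 Hz, coupled sets {0–3} vs {4–7}.
An optional per-class band-power boost exercises spectral rather than
phase contrasts.

What passing tests show — and what they do not: the generator plants class
differences in *band power per channel* and *phase coupling between
channels*; recovery demonstrates that segmentation, connectivity
estimation, adjacency construction, propagation, fusion, optimization and
the leakage discipline are all wired correctly. It does not model volume
conduction, nonstationary coupling, artifacts or inter-subject
variability, so benchmark accuracy says nothing about performance on
clinical recordings.

## Numerical notes and edge cases

- Zero-variance channels get zero correlation entries with a warning, not
  an exception; zero-degree nodes make symmetric normalization fail with
  the channel index in the message.
- Coherence from a single Welch segment is identically 1 — the estimator
  requires averaging to be informative; the segment length/overlap are
  configurable.
- PLI of *identical* channels is exactly 0 by construction: the index is
  computed from the phase-difference series (identical phases subtract to
  exactly zero) rather than from cross-spectra, whose fused
  multiply-accumulate rounding leaves ±1e-17 imaginary residue.
- The logistic gate reaches 0/1 exactly in floating point once |logit|
  exceeds ≈ 37; the (0, 2) openness of the attention score is a statement
  about its linear range.
- Precision/Recall/F1 with zero denominators are reported as 0 with a
  warning.
- EDF output quantizes to 16 bits of the per-channel physical range; the
  HDF5 container stores 32-bit floats and is the lossless interchange
  format.

## Known limitations

- Binary labels only; multi-class would change the head widths and the
  task-adjacency pairing.
- Connectivity is undirected and band-collapsed; no frequency-resolved or
  directed (e.g. Granger-type) graphs.
- The inner-loop selection metric, fine-tuning schedule and optimizer are
  this package's documented choices; alternatives (e.g. selecting on
  validation loss) are easy to wire but not exposed.
- The autodiff core implements exactly the operations this architecture
  needs; it is not a general-purpose framework.
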