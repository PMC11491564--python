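# Methods

## Redundancy metrics

All metrics operate on discretized amplitudes.  A channel value `v` (mV)
maps to bin index `floor((v − anchor) / w)` with width `w = 0.5` mV and
anchor 0 mV by default: half-open intervals `[k·w, (k+1)·w)`, no clipping.
Only the width is essential to the method; the anchor and half-open
convention are fixed here so results are reproducible, and both are
configurable (`BinningConfig`).

Entropies are plug-in (maximum-likelihood) estimates over the empirical bin
distributions.  Joint distributions over channel subsets are held sparsely:
each sample's bin tuple is packed into a single integer key (mixed-radix
over the per-channel bin ranges, with a structured-row fallback if the
radix product would overflow int64) and keys are counted, so cost is
O(n log n) in the sample count and memory is proportional to the number of
*observed* tuples — never exponential in the subset size.

Every conditional entropy is computed by the chain rule
`H(A|B) = H(A,B) − H(B)`; one joint-entropy primitive therefore serves
mutual information, NMI, channel redundancy and set redundancy.  Because
empirical distributions are genuine probability distributions, the plug-in
estimates satisfy `0 ≤ I ≤ min(H(X), H(Y))` and both redundancy measures lie
in [0,1] up to floating-point error; negatives above −1e−12 (MI) and [0,1]
overshoots under 1e−9 (R) are clamped, anything larger raises an
internal-consistency error rather than being silently absorbed.

Entropies default to bits (base 2).  NMI and the redundancy ratios are
base-invariant, which the tests assert between base-2 and base-e runs.

The plug-in estimator is biased upward when the joint histogram is
undersampled: independent channels show small positive redundancy at finite
n.  The intended mitigation is pooling — concatenating many records before
estimating — which is why `RecordCollection`/`concatenate` exist and why
corpus-level figures should be computed on concatenated data.  Tests place
the residual bias for independent channels below 0.02 at n ≥ 1e5 samples and
assert that it shrinks monotonically over n ∈ {1e3, 1e4, 1e5}.  Restricting
a corpus to homogeneous (e.g. healthy/NORM) records before pooling is the
caller's choice via the label field; the metrics themselves are
label-agnostic.

## Lead geometry and selection

The geometry table assigns each lead a plane and projection angle: frontal
limb leads I=0°, II=60°, III=120°, aVF=90°, aVL=−30°, aVR=−150° (hexaxial
convention) and transverse precordial leads V1=115°, V2=95°, V3=75°,
V4=60°, V5=30°, V6=0°.  These are conventional textbook values and are data,
not logic — callers may substitute their own table.  The absolute angle
between two same-plane leads folds direction reversals out (mod 180, then
into [0, 90]).

The shipped fixed subsets (8: I, II, V1–V6; 6: II, aVL, V1, V3, V5, V6;
3: aVR, III, V2; 1: V6) were derived on the PTB-XL corpus and are constants
by design — their derivation depends on that corpus' statistics.  The
generic machinery to re-derive such choices on any corpus is provided:
pair ranking by two-channel set redundancy, most-representative-lead
selection by channel-redundancy argmax, and a minimum-set-redundancy subset
search (exhaustive, capped at 5000 enumerated subsets; greedy beyond, which
is suboptimal-or-equal and tested as such).

## Transforms

Limb-lead derivation uses the Einthoven/Goldberger identities
(III = II − I, aVR = −(I+II)/2, aVL = I − II/2, aVF = II − I/2), which make
I + III − II and aVR + aVL + aVF vanish identically.

The Dower forward matrix (8 leads × 3 VCG axes) and the published
Edenbrandt–Pahlm inverse are shipped as annotated CSV data files.  The
inverse actually applied is the full-precision Moore–Penrose pseudoinverse
of the forward matrix, computed at load time: the published inverse is that
pseudoinverse rounded to three decimals, and using the exact pseudoinverse
makes `inverse_dower ∘ dower_forward` the identity to machine precision
instead of ~1e−3.  A test pins the applied matrix to the published table
within 2e−3 per entry.

PCA is fit once on the concatenated corpus (channel covariance
eigendecomposition via full SVD) and applied globally; per-record PCA is
deliberately not offered so that each component channel has one meaning
across the corpus.  Components are sign-fixed (largest-magnitude loading
positive) purely for reproducibility — redundancy comparisons in the tests
are made on component *sets*, never per-sign values.  PCA-q is defined for
all q up to the channel count: on noise-free dipole data components beyond
the third are numerically null (variance fraction < 1e−9) and are retained
as near-null channels rather than dropped.

The 15-channel augmentation appends the IDT-estimated VCG to the 12 leads.
The three added channels are exact linear combinations of the existing
eight independent leads, so the augmentation can only add shared
information; the tests assert set-R(15) ≥ set-R(12) on seeded fixtures.

## Synthetic dipole generator

Each beat traces a 3-D dipole trajectory built from Gaussian bumps in beat
phase — per axis, a list of (center, width, amplitude-in-mV) components for
the P, Q, R, S, T waves.  Beats are placed at RR intervals
`(60/heart_rate)·(1 + jitter·ε)` with seeded standard-normal ε.  Leads are
plane projections of the dipole: frontal leads project (X, Y), precordial
leads project (X, Z), each at its geometry-table angle perturbed once per
record by a seeded N(0, electrode_jitter) draw (electrode placement varies
between recordings, not within one), plus per-lead white noise.

Defaults and why:

| parameter | default | rationale |
|---|---|---|
| rate, duration | 500 Hz, 10 s | PTB-XL record shape |
| heart rate | 70 bpm | normal resting rate |
| RR jitter | 5 % | normal sinus variability |
| QRS amplitudes | X 0.8, Y 1.3, Z 0.35 mV | frontal electrical axis ≈ +60° (normal axis; lead II carries the tallest R, ≈1.5 mV) |
| noise SD | 0.02 mV | typical post-filter ECG noise floor |
| electrode jitter | 3° | realistic inter-recording placement variation |

The +60° axis matters scientifically: with a normal axis, leads II and aVF
flank the direction of maximum variability while aVL is orthogonal to it,
which is exactly the regime in which NMI(II, aVF) > NMI(II, aVL) and in
which NMI decays monotonically with angle from the principal direction
(`frontal_principal_angle` computes that direction from the frontal
covariance; the angle-ladder tests measure from it).

The five class morphologies (NORM/MI/STTC/CD/HYP) are caricatures — frontal
rotation, amplitude scaling and wave widening per class — that make labels
meaningful for plumbing and class-weight computation.  They claim no
clinical fidelity, and the generator reproduces none of real ECGs'
non-dipolar content, baseline wander, powerline interference or
inter-subject morphology variation.  Passing tests therefore demonstrate
the *estimators and transforms* behave correctly on dipole-plus-noise
signals, not that any specific redundancy percentage will transfer to a
clinical corpus.

## Evaluation

Class weights implement `w_c = (Σᵢnᵢ / n_c)^λ`, the unique algebraic form
consistent with all three defining properties: weights follow the inverse
of class counts, λ > 1 widens the relative spread, λ < 1 flattens it.
Weights are unnormalized (loss frameworks rescale freely).  Choosing λ is a
per-configuration hyperparameter search and is out of scope; any trained
model's predictions can be scored here.

Confusion metrics are computed exactly from TP/FP/TN/FN; ratios with zero
denominators are reported as undefined (None) and excluded from macro
averages rather than coerced to 0.  AUC uses the rank statistic
(trapezoidal ROC with tie-averaging) and AUPRC step-wise precision-recall
integration; both are cross-checked in the tests against a brute-force
concordant-pair count and exact small-sample values.

## Problem sizes in tests

Exact identities and oracle comparisons run on fixtures of ≤ 8 samples ×
≤ 3 channels (where the full joint distribution is enumerable) and ≤ 20
samples for AUC pair enumeration.  Statistical properties of the estimators
use seeded records of 1e5 samples (200 s at 500 Hz), the scale at which
plug-in bias for independent channels drops below 0.02 — large enough for
stable estimates, small enough that the whole suite runs in seconds.

## Known limitations

- Plug-in entropies carry positive finite-sample bias; no bias-corrected
  (Miller–Madow, NSB) estimators are provided, since pooling is the
  intended remedy.
- Redundancy is an i.i.d.-sample measure: temporal structure (beat-to-beat
  repetitiveness) is invisible to it and out of scope.
- The WFDB reader covers single-segment format-16 records with V/mV/uV
  units — sufficient for PTB-XL-style data, not a general WFDB
  implementation.
- Differential (continuous) entropy, k-NN/KDE MI estimators, Kors or
  regression VCG transforms, and any neural-network training are
  deliberately excluded.
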