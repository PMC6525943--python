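# Methods

## Problem setting

Two-class motor-imagery EEG classification from three channels (C3, Cz,
C4).  Imagining a hand movement desynchronizes the sensorimotor μ
(8–13 Hz) and β (13–30 Hz) rhythms over the *contralateral* hemisphere
(ERD) and often synchronizes them ipsilaterally (ERS); left-hand imagery
therefore suppresses band power at C4 and right-hand imagery at C3.  The
pipeline extracts two complementary views of this effect — a 2-D normalized
band-energy difference and a low-dimensional nonlinear embedding of the
samplewise C3−C4 difference signal — fuses them, and classifies with LDA.

## Dual-tree complex wavelet stage

Each trial/channel is decomposed J levels (default J=4) by two parallel
real discrete wavelet transforms.  Level 1 uses an odd-length biorthogonal
bank in both trees, the second tree offset by one input sample; levels ≥ 2
use an even-length orthonormal Q-shift bank in tree A and its time reverse
in tree B, so the two trees' low-pass filters differ by approximately half
a sample.  Complex coefficients are `tree A + i · tree B`.  Subband
*signals* A_J, Dt_J … Dt_1 are obtained by zeroing all other levels and
inverting; the nominal band of Dt_j is [fs/2^{j+1}, fs/2^j] and each
subband is tagged with the canonical EEG wave (δ/θ/α/β/γ) of greatest
frequency overlap — at fs=128, J=4: A4→δ, Dt4→θ, Dt3→α, Dt2→β, Dt1→γ.

Implementation choices:

* Boundary handling is **periodized** inside each tree (signals first
  extended to a multiple of 2^J by right-edge reflection and trimmed after
  inversion).  Periodization makes each tree exactly invertible for *any*
  perfect-reconstruction bank, which gives machine-precision inversion and
  exact subband additivity — properties the tests rely on.  The cost is
  wrap-around mixing confined to the trial edges, outside the analysis
  window in practice.
* The filter catalogue (first level: Antonini 9/7, LeGall 5/3,
  near-symmetric 5/7 and 13/19; later levels: five Q-shift banks of 10–18
  taps) ships as plain-text resources.  Antonini and LeGall are the classic
  CDF 9/7 and 5/3 wavelets (via PyWavelets); the near-symmetric pairs are
  spectral factorizations of maximum-flat half-band filters at the
  catalogued tap counts, and the Q-shift banks are paraunitary-lattice
  designs optimized for quarter-sample group delay and stopband
  attenuation (see `scripts/design_filters.py`).  The lattice
  parametrization makes orthonormality — hence perfect reconstruction —
  exact by construction; design quality shows up as band localization
  (a 10 Hz tone at 128 Hz puts >95% of its subband energy into Dt_3) and
  near shift invariance (<5% subband-energy change under a one-sample
  shift; measured ≲0.1%).
* Default bank: Antonini + Qshift_c.

## Energy features (F1)

Within the selected time block, a window of 2·fs samples slides one sample
at a time.  Per window, each subband's energy is divided by the summed
energy of all J+1 subbands (so normalized energies sum to one — scale
free).  Averaging each sequence and subtracting C4 from C3 gives
AE_wv per wave; `F1 = [AE_α, AE_β]`.  Under left-hand ERD, C4's α energy
share drops, so AE_α rises; right-hand imagery mirrors it.

**Time block.**  The analysis window (default 4 s) is chosen automatically
by sliding over the post-cue interval and maximizing the integrated class
contrast |(P_L^C3 − P_L^C4) − (P_R^C3 − P_R^C4)| of moving-average-smoothed
(fs/4 samples) mean-squared-amplitude curves; ties go to the earliest
start.  A manual override — seconds or inclusive sample indices — always
wins, since practitioners often pick this window by inspecting the average
power curves.  All internal indexing is 0-based half-open; inclusive sample
overrides are converted at the boundary.

**Wave selection.**  The subband feeding the embedding is chosen per
training set by the Fisher ratio of each subband's AE feature; every
subband scoring at least `wave_fraction` (default 0.8) of the best is kept,
ties resolving toward lower frequency, with a manual override available.
When several waves are selected their difference vectors are concatenated.

## Nonlinear features (F2): landmark MVU + incremental extension

Per trial, the samplewise C3−C4 difference of the selected subband over the
time block forms a high-dimensional vector (551 samples for a 4.3 s block
at 128 Hz).  Maximum variance unfolding maximizes total variance subject to
preserving local neighbor distances, as a semidefinite program over a Gram
kernel; the landmark variant shrinks the SDP to an m×m kernel L and
propagates landmark coordinates to all n samples through Q built from
locally linear reconstruction weights.

* **Weights W** (training, Eq.-level): each sample is reconstructed from
  its r nearest neighbors with sum-to-one weights from the local Gram
  system; a ridge of 1e−3·trace(G)/r is added when the Gram's condition
  number exceeds 1e10 (r routinely exceeds the local manifold rank), and a
  coincident neighbor receives the exact indicator solution.
* **Q**: with Λ = (I−W)ᵀ(I−W) partitioned by landmark/non-landmark index
  sets, the landmark rows of Q are the identity and the remaining block is
  −Λ₂₂⁻¹Λ₂₁, the minimizer of the reconstruction functional tr(QᵀΛQ).
  Landmarks default to the first m samples in input order.
* **SDP**: maximize trace(QLQᵀ) subject to embedded neighbor distances not
  exceeding input distances on the symmetrized k-NN graph, global
  centering, and L ⪰ 0.  The centering constraint forces q = Qᵀ1 into the
  kernel's null space, so the program is solved over the subspace
  orthogonal to q (zero-distance constraint directions are folded into the
  null space the same way; if nothing remains, L = 0).  The solver is an
  in-house dense log-barrier path-following method (damped Newton in vec
  coordinates, strictly feasible iterates, relative duality-gap target
  1e−8, hard failure — never a silent one — if it stalls early).  Iterates
  being interior guarantees the distance inequalities and PSD-ness at the
  returned solution; centering is exact by construction.
* **Embedding**: landmark coordinates are √λ_k·v_k for the d largest
  eigenpairs of L (so YᵀY reproduces the kernel), with a deterministic
  eigenvector sign convention (largest-magnitude component positive);
  all samples then follow through Q.
* **Out-of-sample**: a new vector's w nearest training samples (exact
  brute-force search; ties toward smaller index) are found, the same
  regularized sum-to-one solve gives weights IW, and
  y_new = Σ IW_j y_j.  No SDP at test time; training data X and embedding
  Y are retained in the model for this purpose.

Default parameters r=52, m=14, d=5, k=24, w=4, clamped to the data size
when n is small.  Accuracy is insensitive to w (measured spread < 1
percentage point over w ∈ {2,…,12} on the synthetic benchmark).

Known behavior: with few landmarks the kernel is confined to span(Q), so
some neighbor distances *shrink* by tens of percent in the embedding (they
can never stretch — the constraint is one-sided).  Unfolding quality also
depends on landmark coverage; because landmarks are the first m samples,
inputs ordered along the manifold (rather than arbitrarily, as trials are)
concentrate landmarks at one end and degrade the embedding.

## Fusion, classification, evaluation

`F = [100·F1 ; F2]` — the energy features are roughly two orders of
magnitude smaller than embedding coordinates, and the fixed ×100 rescaling
brings them onto a common footing.  Classification is two-class LDA with
equal priors and pooled covariance; when the pooled covariance's condition
number exceeds 1e8 the estimate is shrunk toward scaled identity with a
small fixed coefficient (an automatic Ledoit–Wolf estimate can collapse to
zero shrinkage on degenerate data).  A plug-in classifier factory in the
config lets any sklearn-style estimator replace LDA, but only LDA is a
tested deliverable.

Evaluation is stratified 10-fold cross-validation: per fold, time block,
waves, W/Q/L and the classifier are fitted on training trials only, and
test trials pass through the incremental embedding — never a refit.  A
config flag (`selection_on_full_set`, default off) exists solely to make
the leakage contract testable.  Cohen's kappa is computed from the pooled
confusion matrix (for balanced data kappa = 2·acc − 1 exactly).  The
two-sample t-test uses the pooled-variance statistic with n_a + n_b − 2
degrees of freedom and a one-sided upper tail by default ("is method B
better?"); a two-sided option is provided since published analyses are
often two-sided.

## Synthetic generator

Each trial is 1/f^α background noise (α=1) plus band-limited μ and β
noise rhythms at each channel (fourth-order Butterworth-filtered white
noise; band-limited noise rather than pure tones keeps subband energies
non-degenerate).  During the cue interval (default 3–7 s of a 9 s trial at
128 Hz, mirroring classic cued-imagery protocols) the contralateral
channel's rhythm amplitudes are multiplied by √erd_factor and the
ipsilateral by √ers_factor, with 0.25 s raised-cosine ramps so no step
edges leak across subbands.  Defaults: μ amplitude 1.0 and β 0.7 at C3/C4
(half that at Cz, task-independent), background 1.0, erd 0.5, ers 1.2 —
rhythm-to-background ratios at which the rhythms are clearly visible in
the average power curves, as for a good BCI subject.  Everything is drawn
from one seeded generator, so identical configs are bit-reproducible.

What it does *not* emulate: eye/muscle artifacts, inter-trial
nonstationarity, volume conduction between channels, subject variability,
or realistic spatial covariance.  Passing the end-to-end tests therefore
shows the chain recovers a planted spectral effect of realistic size under
realistic noise colors — not that it reaches any particular accuracy on
real recordings.

## Problem sizes and tolerances

The reference checks use: 200 trials (9 s, 128 Hz) for the end-to-end
planted-effect (erd 0.3 → accuracy ≥ 85%, kappa ≥ 0.7) and null
(accuracy 40–60%) runs; curled-arc toys of 10–40 points for the embedding
properties; 25 refits for the incremental-vs-refit comparison.  Key
numerical targets: reconstruction error < 1e−10, subband additivity
< 1e−8 relative, energy normalization < 1e−12, weight-solver agreement
with an independent constrained solver < 1e−8, SDP constraint
slack/centering ≤ 1e−5, landmark-chain-vs-full-MVU Procrustes residual
< 1e−3.
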