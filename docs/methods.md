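# Methods

`cortconn` estimates directed, frequency- and time-resolved cortical
connectivity from multichannel epoched EEG recorded under two task
conditions (a control condition and a test condition), and tests the
condition contrast nonparametrically across subjects.  This note records
the models and procedures implemented, the defaults and why they were
chosen, and what the synthetic validation data do and do not establish.

## Pipeline overview

Per subject: channel-space cleaning → cLORETA source localization on a
spherical head model (per-epoch regularization) → max-power collapse of
each region of interest (ROI) to one representative current time series →
sliding-window multivariate autoregressive (MVAR) modeling per condition →
short-time direct directed transfer function (SdDTF).  Across subjects:
cross-subject mean connectivity tensors per condition, a condition-mixing
permutation surrogate distribution, rank p-values, Benjamini–Hochberg FDR
control, and a masked test-minus-control difference map.

## Channel-space cleaning

* **Band-pass filter**: zero-phase FIR (forward–backward `filtfilt`),
  default 1–55 Hz.  FIR with two-pass application is used for its exactly
  linear (net zero) phase: phase distortion at this stage would corrupt
  the lag structure on which causal MVAR modeling rests.  The kernel
  length targets a transition width of one low-edge bandwidth but is
  capped at a third of the epoch length so the filter remains applicable
  to epoched data; on short epochs the effective high-pass transition is
  correspondingly wider.  The per-trial mean is removed explicitly.
* **Common average reference**: idempotent projection; reduces rank by 1,
  which the ICA stage handles by PCA rank reduction.
* **Kurtosis rejection**: kurtosis per channel (over concatenated trials)
  and per trial (over concatenated channels), Z-scored across the
  respective population; |Z| > 5 flags the entry.  The procedure is fully
  automated, but every statistic is returned in an audit report and an
  override list can force retention — the traditional visual-inspection
  step becomes a logged, reviewable decision.
* **Infomax ICA**: data are sphered and decomposed with plain (logistic)
  Infomax (natural-gradient ascent with annealing, as provided by
  `mne.preprocessing.infomax`); the extended variant is optional.
  Components are retained when their scalp map fits a single
  fixed-orientation dipole on the source mesh with residual variance
  ≤ 0.15 (exhaustive scan over mesh vertices, least-squares moment per
  vertex, lowest-index tie break); retained components are re-projected
  to channel space.  Recovery is claimed only up to permutation and
  scaling of sources, and is measured by the Amari index.
* **Resampling**: polyphase anti-aliased decimation, default to 128 Hz.

## ROI definition by IC clustering

Components pooled across subjects are described by seven feature blocks:
scalp map, ERP, Welch power spectrum, event-related spectral perturbation
(ERSP, short-time Fourier power in dB relative to a baseline window —
default the first quarter of the epoch), inter-trial coherence (ITC,
magnitude of the trial-mean unit phasor), a trials × time ERP-image
downsampled to a fixed 16 × 16 grid, and the fitted dipole location.
Each block is PCA-reduced (default 10 dimensions) and scaled to unit total
variance before concatenation — the blocks have no common physical units,
so equal-variance weighting is the neutral choice — and the concatenation
is PCA-reduced again to 10 dimensions.  K-means (Lloyd's algorithm,
k-means++ seeding, 20 restarts, Euclidean metric) groups the components,
default K = 14; within-cluster dispersion is reported so alternative K
can be compared.  Cluster centroids are labeled by the nearest named
region (Euclidean distance to region mean position); a cluster whose
member dipoles split across hemispheres may receive both members of a
lateralized region pair, and the three midline regions (ACC, SMA,
precuneus) are defined with merged bilateral gridpoint sets from the
start.

## Head model and lead field

The source space is a subdivided icosahedron (default subdivision 3: 642
vertices) scaled to 92 % of the brain-shell radius, with one dipole per
vertex oriented along the outward normal.  Volume conduction is a
three-shell concentric sphere (brain/skull/scalp radii 0.087 / 0.092 /
0.100 m; conductivities 0.33 / 0.022 / 0.33 S/m).  Scalp potentials are
evaluated by the Legendre series for a dipole in a multilayer sphere,
with the layered structure entering through per-degree 2 × 2
transfer-matrix products (200 series terms by default).  Two independent
checks validate the implementation: the equal-conductivity limit matches
a closed-form homogeneous-sphere potential (derived by summing the series
with generating-function identities) to 1e−6 relative, and the
three-shell potentials match MNE-Python's sphere model to series
truncation accuracy.  The lead field is average-referenced per source.
The surface Laplacian is the uniform graph Laplacian (degree minus
adjacency) by default; cotangent weights are available.

The 64-electrode montage is a deterministic Fibonacci spiral over the
upper scalp (z ≥ −0.25 · R), a stand-in for an extended 10–20 layout.
The packaged nine-region map (bilateral inferior occipital, superior
parietal and precentral motor regions, plus merged midline ACC, SMA and
precuneus) places seeds at plausible angular positions on the sphere;
regions are all vertices within a fixed radius of the seed, with overlap
resolved by nearest seed.

## cLORETA inverse with per-epoch regularization

The inverse problem is Tikhonov-regularized least squares,
`J = (KᵀK + λ²HᵀH)⁻¹KᵀΦ`, with H the surface Laplacian.  Two
implementation choices matter:

* **Proper prior.** The pure Laplacian penalty is a semi-norm: its
  constant null space is unpenalized, and on a *closed* source surface a
  strongly regularized solution collapses onto a spatially uniform
  current field that fits the data freely — every vertex inherits the
  same time course and ROI signals become meaningless.  The solver
  therefore uses the proper prior `HᵀH + ε I` with
  `ε = 0.01 · trace(HᵀH)/G` (a weak minimum-norm term).  The literal
  semi-norm transform remains available as `cloreta_transform` and is the
  form checked against a dense-inverse oracle.
* **Fast per-epoch solves.** With `HᵀH + εI = RᵀR` and an SVD of
  `K R⁻¹`, the transform, the influence matrix, GCV scores and the EM
  update are all O(C²) per λ, so λ is re-estimated for every epoch.

λ is selected per epoch by generalized cross-validation on a 30-point
log-spaced grid spanning `median(s) · [1e−4, 1e2]`, where `s` are the
singular values of the transformed lead field.  The grid is scaled by the
singular spectrum rather than by the data because GCV is scale-invariant
in Φ and λ's natural units are those of the operator.  An optional EM
refinement treats sensor-noise and source-prior variances as the two
components of a hierarchical Gaussian model (prior confined to the
identified rank-C subspace), iterates their closed-form updates, and
returns λ² as the noise-to-prior variance ratio; the model evidence is
non-decreasing across iterations and is asserted as such.  On data
simulated from that model the EM recovers a known λ² within 25 %
(median).  Localization runs independently per epoch so regularization
tracks per-epoch signal-to-noise.

Each ROI is collapsed to the time series of its maximum-mean-square-power
gridpoint.  By default the power is pooled over all epochs
(`scope="per_subject"`), keeping the network node fixed across the trial
ensemble as required for trial-ensemble MVAR fitting; per-epoch selection
is available.  Ties break to the lowest vertex index.

**Resolution caveat.**  cLORETA is a low-resolution method: at the
GCV-selected regularization its point-source peak is displaced by roughly
2 cm on this geometry.  Exact-vertex recovery of a planted dipole is
therefore benchmarked on the 42-vertex mesh (~44 mm spacing, comparable
to the method's resolution) with sources drawn from vertices under the
sensor cap — a dipole with no electrodes near it is unresolvable by any
inverse method, and real cortex does not extend below the cap.  Under
those conditions recovery at SNR 10 dB is essentially perfect; on finer
meshes misses become nearest-neighbor displacements, and sources outside
the covered region mislocalize systematically.

## Sliding-window MVAR

ROI ensembles are detrended per trial, z-scored per channel per trial,
and ensemble-normalized per timepoint (removing the phase-locked evoked
component).  VAR models are fitted in sliding windows (defaults 550 ms
length, 10 ms step) by the Vieira–Morf lattice: order-recursive
forward/backward reflection matrices with geometric-mean (Cholesky)
normalization, accumulating error covariances across the trial ensemble
rather than concatenating trials.  The lattice yields every order up to
the maximum in one pass, which makes the order scan cheap.  A
data-to-parameter ratio below 10:1 triggers a warning.

Model order is chosen by six information criteria (AIC, small-sample
corrected AICc, Schwarz–Bayes, Hannan–Quinn, log final prediction error,
and a minimum-description-length criterion with penalty
`k(ln n + ln ln n)/n`, deliberately heavier than Schwarz), each computed
from the lattice residual covariances over candidate orders 1–30,
averaged over a few evenly spaced windows; the selected order is the
floor of the mean of the six argmins, determined independently per
condition.

Validation per window: residual autocorrelations against ±1.96/√n bounds
(pass = 95 % inside), multivariate Box–Pierce, Ljung–Box and Li–McLeod
portmanteau statistics against χ² with M²(h−p) degrees of freedom
(default h = min(20, w/4) lags), percent consistency
`PC = 100(1 − ‖r_sim − r_real‖/‖r_real‖)` over stacked auto/cross
correlations up to 10 lags of a model-simulated ensemble with matched
size, and the stability index (log spectral radius of the companion
matrix; negative = stable).  On under-modeled data the expected pattern —
whiteness rejected while consistency stays high — is reproduced and
tested.

## SdDTF

Per window, the transfer matrix `H(f) = [I − Σ A_k e^(−i2πfk/fs)]⁻¹`, the
cross-spectrum `S = H Σ Hᴴ / fs`, and the partial coherence
`P_ij = G_ij/√(G_ii G_jj)` with `G = S⁻¹` are evaluated on a fixed grid
(default 2–50 Hz, 1 Hz).  The SdDTF is

    eta²[i←j](f, t) = |H_ij|² |P_ij|² / Σ_{f',k,l} |H_kl|² |P_kl|²

with the normalizing sum running over all node pairs (diagonal included)
and grid frequencies within the window, so the tensor sums to exactly 1
over (sink, source, frequency) per window.  The squared-magnitude
numerator is the default because it makes the quantity an exact
partition of unity and matches the established SdDTF literature; a
"literal" mode with an unsquared numerator (a monotone per-window
rescaling) is available and flagged in output metadata.  The diagonal is
masked at reporting time only.  Partial-coherence weighting is what
suppresses indirect (cascade) flow: on a 1→2→3 chain the 1→3 share is
reduced by two or more orders of magnitude relative to a DTF without the
weighting.

## Permutation statistics

For each condition, each subject contributes R (default 300) surrogate
tensors computed by rerunning the full connectivity path on ensembles
that mix control and test epochs with equal representation at the
evaluated condition's ensemble size (odd sizes alternate the extra
epoch).  Surrogates are averaged across subjects position-wise by
replicate index (any fixed pairing is exchangeable under the null) and
sorted; the observed statistic is the cross-subject mean tensor.  Rank
p-values are two-sided by default — the alternative is a change in either
direction — with one-sided modes available.  BH-FDR runs over all
off-diagonal spectro-temporal positions of a condition's tensor (global
pooling; per-pair pooling is available).  The difference map is
`masked(test) − masked(control)` with non-significant entries contributing
zero.  The whole stage is bit-reproducible from its seed: per-subject,
per-condition generator streams are spawned from the master seed.

## Synthetic cohort

The generator emulates the study design the pipeline targets: 10
subjects, two conditions with 96 control and 192 test trials per subject
(configurable; the originating task description gives both 256 total and
a 96 + 192 split, which disagree — both counts are exposed and the split
is the default), 1 s epochs at 128 Hz, 64 channels.  Nine VAR source
nodes (order 2) sit at representative vertices of the nine regions:
alpha-band AR(2) self-dynamics (spectral peaks 9–12 Hz, pole radius
0.75), a static directed backbone (occipital→parietal, parietal→precuneus,
precuneus→SMA, SMA→ACC, coefficients 0.2–0.25), one planning-only edge
(R Par→SMA, switching off at the 0.5 s planning/execution split) present
in both conditions, and one condition-specific planted edge (ACC→L Mot,
coefficient 0.4) present only in the test condition.  Sources are
projected through the spherical lead field at 10 nA·m moment scale with
white sensor noise at 10 dB total SNR; per-subject coupling coefficients
are jittered by 5 % (multiplicative, unstable draws resampled).  Trials
are independent realizations with a 10·order burn-in; innovations are
Gaussian.  Optional artifact injection adds rank-1 frontal blink
transients (Poisson in time) and heavy-tailed spikes on a single channel,
giving the rejection and ICA stages realistic work.

What the generator does **not** emulate: 1/f background spectra beyond AR
coloring, volume-conducted subcortical sources, correlated sensor noise,
electrode drift, or between-subject head-geometry variation (all subjects
share one head model).  Passing tests therefore establish internal
correctness and statistical calibration of the method under its own
assumptions, not performance on real recordings.

## Problem sizes used in validation

The test suite and the acceptance script scale the study design down so
every property is measured from scratch in a few minutes on one CPU: the
default head model for end-to-end runs uses the 642-vertex mesh;
cohort-level checks use 32 control / 64 test trials per subject, 100
permutations, a 100 ms window step and a 4 Hz frequency grid; the
planted-edge sensitivity is measured over repeated independently seeded
cohorts, scoring a detection when the planted pair is the largest-
magnitude cell of the integrated difference map with the correct sign.
These sizes are the package's validation configuration, chosen as the
smallest at which the measured properties are stable; all are ordinary
function arguments and scale up directly.

## Known limitations

* The spherical head model preserves the structure of the inverse
  problem but not individual anatomy; no claim is made about anatomical
  localization accuracy on real heads.
* Exact-vertex localization degrades to nearest-neighbor displacement on
  meshes finer than the method's intrinsic resolution (see above).
* The Vieira–Morf lattice is unregularized; short windows with many
  nodes need the 10:1 data-to-parameter guard.
* Rank p-value resolution is 1/(R+1); with global FDR pooling, weak
  effects need either many permutations or a coarse spectro-temporal
  grid to survive correction.
* Nonlinear and nonstationary-within-window dynamics are outside the
  model class; the validation suite shows the expected diagnostic
  signature (whiteness failure with high consistency) rather than
  attempting to model them.
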