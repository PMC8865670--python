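# Methods

`laminet` decomposes time- and frequency-resolved directed cortical
connectivity into concurrent feedforward and feedback networks, and
characterizes each network's laminar profile, spectrum, temporal dynamics,
functional hierarchy, receptive-field (RF) organization and relation to
spiking.  This note documents the models, the synthetic ground-truth world
used for validation, the numerical choices, and what the tests do and do not
establish.

## Analysis pipeline

### Time-varying MVAR (adaptive Kalman/RLS)

Laminar bipolar LFP epochs (trials × channels × time, 250 Hz) are modeled as
a time-varying vector autoregression of order `p` (default 15 samples =
60 ms).  At every time point all trials are treated as repeated measurements
of one regression, and the recursion

    R(t) = c R(t−1) + Z(t)'Z(t)/N,   r(t) = c r(t−1) + Z(t)'X(t)/N,
    A(t) = R(t)⁺ r(t)

down-weights the past exponentially with the filter factor `c` (default
0.98, effective memory ≈ 1/(1−c) = 50 samples = 200 ms).  The pseudo-inverse
truncates eigenvalues below 1e−8 of the largest.  Two implementation details
matter in practice:

* **Warm start.** A cold recursion leaves a large ramp-in transient over the
  first ~1/(1−c) samples which, after iPDC, appears as a spurious
  epoch-onset component in the group tensor.  The recursion is therefore
  warm-started by cycling over the earliest (baseline) segment for ~3 time
  constants before the recorded pass.
* **Residual covariance.** Σw is estimated from one-step-ahead errors, both
  as a global average (used by iPDC) and as an exponentially-weighted
  per-time estimate.

Model order selection compares the model-implied spectra with a
complex-Morlet reference in log units after per-channel mean-log alignment
(the two estimators carry different unit factors); ties break to the
smallest order.

### iPDC and the group tensor

The Fourier-transformed coefficients `Abar(f,t) = I − Σ_k A_k(t) e^{−i2πfk/fs}`
are column-normalized into the information partial directed coherence

    iPDC_ij = |Abar_ij| σ_ii^{−1/2} / sqrt(abar_j^H Σw^{−1} abar_j),

evaluated at 1…100 Hz (1-Hz grid) and every 4-ms time point.  With diagonal
Σw this reduces to the generalized PDC whose squares sum to 1 over targets.
Per-animal magnitudes are unfolded to source layer × target layer × time ×
frequency × between-area connection (within-area blocks dropped; 30
connections for 6 areas) and averaged over the animals that recorded both
areas.

**The estimation floor.** Because magnitudes of noisy complex estimates are
biased upward, the tensor carries a positive background everywhere
("floor"), of order `E|noise| ≈ σ_Abar √(π/2) / colnorm(f)`, where
`colnorm(f)` is the column norm of the intrinsic dynamics.  This floor is a
property of absolute-valued PDC estimators in general, not of this
implementation; it is nearly constant over time and connections, follows
~1/colnorm(f) in frequency (a shallow power law), and is uniform over
layers.  Its consequences for decomposition and selection are discussed
below — they drive several design decisions.

### Nonnegative PARAFAC

The 5-way tensor is decomposed by nonnegative CP/PARAFAC fitted with
HALS-style alternating least squares: random or SVD-magnitude
initialization, column-wise nonnegative updates, dead components reseeded,
reconstruction error non-increasing.  Stopping: relative fit change < 1e−8
or 2000 iterations (diagnostic fits use looser settings); `fit_parafac`
keeps the best of several restarts.  On exit the source-layer, target-layer,
frequency and connection loadings are scaled to variance 1 (scale division
only, no centering, so the reconstruction is unchanged) and the component
scale is carried by the temporal loadings; components are ordered by
descending amplitude share (mean temporal loading over the sum).

Caveat of the variance-1 convention: a component whose loadings are nearly
constant across a mode (such as the floor-dominated background component)
receives a very large normalized column and a correspondingly tiny temporal
loading; its amplitude share is then close to zero even though it may carry
most of the tensor's energy.  The share statistic is therefore meaningful
for the stimulus-specific networks but understates the background.

### Component-number selection

The classical recipe combines Corcondia, explained variance, MSE,
convergence and visual inspection.  On tensors with a dominant additive
floor two of these indicators degenerate, for reasons that are structural
rather than numerical:

* **Explained variance** is dominated by the floor's DC term; the EV curve
  is nearly flat in K (the specific networks each add < 0.5 % EV), so
  marginal-EV thresholds select K=1–2 regardless of the true structure.
* **Corcondia** requires well-conditioned factor matrices.  Broad
  nonnegative loadings are strongly collinear in the uncentered sense
  (cosines > 0.9), and the background component is nearly constant in four
  modes; the least-squares core then explodes and Corcondia is hugely
  negative at *every* K.

The default rule therefore gates on the two indicators that remain
informative, both of which mirror the original analysis logic ("including
more components resulted in high correlations between some of them"; the
bootstrap consistency check):

1. **Between-component correlation** — at the first K beyond the true count,
   the extra component duplicates existing structure; the median (over
   diagnostic bootstraps) maximal between-component correlation of
   concatenated (a, b, d, e) loadings must stay below 0.8.
2. **Bootstrap stability** — components are refit on random animal subsets
   and aligned by optimal assignment; every component's median
   intra-bootstrap consistency must exceed a threshold (default 0.7).
   Noise-capturing components do not replicate across subsets.

K* is the largest candidate satisfying both (convergence is also required);
Corcondia, EV and MSE are computed and logged for every candidate.

### Statistics on loadings

* Laminar significance: per bootstrap the layer vector is normalized to
  sum 1; a layer is flagged when the 95 % bootstrap CI lower bound exceeds
  the uniform value 1/n_layers.
* Temporal dynamics: percent change from the pre-stimulus baseline with
  one-sided t-tests per post-stimulus time point, Bonferroni-corrected.
* Frequency profiles: nonlinear least squares of power-law `c·f^−β`,
  lognormal `c·LogN(μ,σ)` and exponential `c·e^{βf}` curves; lowest MSE
  wins.  An amplitude parameter is included for the lognormal because
  loadings are not normalized densities.
* Rhythmic modulation: linearly detrended Fourier amplitude of the
  post-stimulus temporal loading.

### Functional hierarchy

From a component's connection loadings arranged as `e[i, j]` (j → i), the
directed asymmetry index `DAI_ij = (e_ij − e_ji)/(e_ij + e_ji)` is scaled by
2.5 (mapping its attainable range onto ±2.5, i.e. as many levels as areas)
and shifted by +3.5 so the range becomes hierarchy levels [1, 6]; the score
of area i is the mean of its (target-)row.  Net drivers obtain the lowest
scores.  A literal per-target-row shift (each row's minimum to 1) is
available as an option but is not the default: it removes all between-area
level information (only within-row spread survives) and does not reproduce
the qualitative behavior the method exists for — drivers at the bottom,
monotone scores along a pure chain, ranking reversal under connection
reversal — all of which hold for the fixed shift.

### RF and spiking analyses

RFs are detected per site by permuting stimulus-position labels (statistic:
maximum position-mean response; add-one p-value) with centroids as
response-weighted means over above-half-max pixels.  Reconstructed
connection strengths (the factorized average of the rank-1 component
reconstruction) are regressed on centroid distances with random intercepts
for bootstrap and connection (ML fit; likelihood-ratio test against OLS).
Spikes from units with SNR > 3 are pooled per (area, layer) into 4-ms bins
(L1 excluded by default for lack of spiking) and correlated with
bootstrapped temporal loadings; a site is significant when the central 95 %
of the bootstrap correlation distribution excludes zero.  Note the CI-based
rule tests the stability of the observed correlation across bootstrap
models, so its error control relies on bootstrap scatter being commensurate
with estimation uncertainty.

## The synthetic world

The generator expresses ground truth directly as a time-varying MVAR
coefficient array, so the estimation target of the downstream pipeline is
exact by construction.  Channels carry heterogeneous intrinsic AR(2)
dynamics (poles ~0.55–0.75 and 0.15–0.35, seeded); identical intrinsic
poles would make the companion spectrum degenerate and the coupled system
hypersensitive to coupling strength.  Each of the four planted networks is
a set of directed couplings between (area, layer) channels: a rank-1 layer
block × connection weights × a short FIR kernel × a stimulus-locked
envelope.

Three design points deserve emphasis:

* **Kernels are designed in iPDC units.**  The iPDC of a coupling is its
  frequency gain divided by the source column norm, which is small at low
  frequencies.  Designing the kernel against `target_iPDC(f)·colnorm(f)`
  therefore plants exactly the intended iPDC spectrum while keeping
  low-frequency coupling gains (and hence instability through the intrinsic
  resonance) small.  Peaks are calibrated on the 1-Hz grid: the gamma
  network peaks at exactly 38 Hz (high contrast) / 26 Hz (low contrast);
  the feedback networks peak at 5–6 Hz.
* **Stability is enforced by construction.**  After assembly the coupling
  contribution is rescaled by a single bisected scalar until the companion
  spectral radius is ≤ 0.95 at every checked time point (the intrinsic
  dynamics are left untouched; a per-lag geometric rescale would low-pass
  the kernels).
* **The dominant network is weak-but-broad by necessity.**  A dense
  all-connection web peaking at low frequencies cannot be strong in any
  stable MVAR: the collective (operator-norm) gain of its layer blocks,
  multiplied around loops through the intrinsic resonance, is bounded near
  one.  The planted scale-free feedforward web therefore has per-entry
  couplings at or below the estimation floor, and the fitted model recovers
  it merged with the floor as one broad, power-law, near-flat-in-time
  dominant component whose anisotropies (V1 as driver, L4/L5 source bias)
  are inherited from the planted web.  This mirrors the real-data situation:
  a dominant scale-free component with relatively uniform laminar loadings
  is exactly what an absolute-iPDC floor plus a broad weak web would
  produce, and a green recovery test for the specific band-limited networks
  does **not** establish that the dominant component's fine structure is
  estimable at single-connection resolution.

Default geometry: 6 areas (V1, LM, RL, AL, PM, AM) × 6 layers at 250 Hz,
epochs −300…+1000 ms, 300 trials per contrast (simulation studies use 200),
additive measurement noise at 7.5 % of signal RMS, per-animal coupling-gain
jitter ±10 %.  A reduced 3-area × 3-layer configuration with the same four
networks supports fast tests.  Spiking is inhomogeneous Poisson with rates
`base·(1 + Σ g_k env_k)` clipped at zero, and ~25 % of units drawn below
the SNR-3 inclusion threshold.  RF maps are Gaussian bumps on the
120° × 95° stimulation field; convergent/divergent geometry is arranged by
classical MDS on a target distance matrix derived from the planted
connection weights.

## Numerical choices and degenerate inputs

* Anti-alias filter: zero-phase Kaiser FIR, cutoff 0.45·fs_target,
  ≥ 60 dB by the new Nyquist; integer decimation only.
* Bipolar derivation sign: below − above.
* CSD: plain second difference, edge channels dropped; no spatial smoothing.
* iPDC: pairs with zero reciprocal strength give DAI 0; singular Σw raises.
* PARAFAC: all-zero tensors raise; dead components are reseeded; an exactly
  constant loading column falls back to RMS normalization.
* Corcondia is 100 by convention at K=1.
* Permutation p-values use the add-one estimator (never exactly zero).

## Known limitations

* The estimation floor of absolute iPDC is reproduced, not removed; all
  selection and recovery behavior is validated in its presence.
* Amplitude shares follow the temporal-loading convention and understate
  near-uniform (background-merged) components.
* The spike–network significance rule is a stability test across bootstrap
  models, not a frequentist test against independent noise.
* Biophysical LFP genesis (volume conduction, dipole geometry) is out of
  scope; synthetic epochs are MVAR realizations.
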