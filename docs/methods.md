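# Methods

## The circuit

The generative model is a convolution-type neural mass model of a
thalamocortical loop. Motor cortex contributes four masses — superficial
(SP), middle (MP) and deep (DP) pyramidal populations plus a shared
inhibitory interneuron pool (II) — and thalamus two: excitatory relay
(REL) and inhibitory reticular (RET) cells. Each mass carries two states,
mean membrane potential v and its rate of change, and responds to afferent
firing through a critically damped second-order kernel with time constant
T; an isolated mass has impulse response (t/T)·e^(−t/T), peaking at t = T.
Firing is the centred logistic S(v) = 1/(1+e^(−Rv)) − ½, so the origin is
an exact fixed point of the unforced circuit and the operating-point gain
is R/4.

Cortical intrinsic coupling comprises the reciprocal pairs SP↔MP, SP↔DP,
SP↔II, MP↔II, DP↔II and four self-edges (14 directed edges); thalamic
intrinsic coupling is REL↔RET plus a RET self-edge. Edges out of II or RET
are GABAergic (negative); all self-edges model laminar-specific recurrent
inhibition and are negative irrespective of the cell type. Corticothalamic
edges DP→REL and DP→RET always exist; the thalamocortical afferents from
REL define the 9-way architecture factor. Intrinsic edges conduct with
1 ms delay, extrinsic (between-structure) edges with 8 ms; the delays are
fixed, not fitted.

State vectors are stored as `[v(6); v̇(6)]` in population order
(SP, MP, DP, II, REL, RET). Couplings are in Hz; time constants and delays
in seconds internally, serialized in milliseconds (the units the priors
are quoted in).

### Priors

Every positive parameter is expressed as prior-mean × e^θ with θ ~ N(0, σ²)
(noise log-amplitudes are additive in θ). Prior means: all 800 Hz for the
thalamic and extrinsic couplings; 8 ms time constants; sigmoid slope 2/3;
contribution weights J = (0.6, 0.2, 0.2) over (SP, MP, DP); observation
gain 1; condition effects B = 0. Prior variances per block: cortical
couplings and extrinsic couplings 1/16, thalamic couplings 1/64, cortical
time constants 1/16, thalamic 1/64, slopes 1/32 (cortex) and 1/16
(thalamus), B 1/8, noise amplitudes 1/128, gain 64, J 1/16, and the data
log-precision hyperparameter N(12, 1/32).

The 14 cortical coupling magnitudes form the multiset {800×9, 400×4,
200×1}. Their assignment to individual edges is not uniquely determined by
the prior table alone, and it matters: most assignments leave part of the
circuit low-pass rather than beta-resonant. The package fixes one default
assignment (see `circuit.CORTICAL_PRIOR_MEANS`), chosen once by exhaustive
search over the ~10⁴ admissible assignments for three properties of the
prior circuit: (a) stability under all nine architectures, (b) an interior
spectral peak inside 15–35 Hz for all six populations and for the observed
channel, and (c) the reported direction of condition effects (the
reference modulation pattern raises beta power; increasing the MP→SP
effect under weak REL→RET raises beta power monotonically and steeply).
The assignment is configuration, not a claim: pass any `gamma_mmc` vector
to override it.

## Spectral forward model

`find_fixed_point` solves the stationary voltage equation (the origin, for
zero drive) and verifies local stability; `linearize` returns the
first-order delay-corrected system matrix A = (I + Σ_d d·J_d)⁻¹ Σ_d J_d,
which is used for stability checks and flagged-instability decisions
throughout.

Predicted spectra, however, use the exact delay-resolved resolvent

    H(f) = C · (2πif·I − J₀ − J_intr e^(−2πif·d) − J_extr e^(−2πif·D))⁻¹ · B_in

evaluated per frequency. The first-order operator is accurate for the
eigenvalue problem but materially overestimates peak power when an 8 ms
delay meets a sharply resonant beta mode (≈40% excess band power, 2.3×
peak excess at the default operating point); the exact resolvent agrees
with delayed stochastic simulation to within a few percent, which is the
accuracy standard the cross-validation tests enforce. Inputs enter at MP
and REL with spectral density G_u(f) = e^{α_s} + e^{β_s}/f; the observed
channel is L·(J·v_pyramidal) plus channel noise G_n(f) = e^{α_c} + e^{β_c}/f.
All densities are one-sided PSDs (units²/Hz), directly comparable to
`scipy.signal.welch` estimates. A frequency grid of 4–48 Hz at 0.5 Hz is
the default: it brackets the beta band with margin at the resolution the
500 ms epochs support. Grids containing 0 Hz are rejected (the pink term
diverges).

Condition effects apply only to the high-beta prediction:
`coupling_HB = coupling_LB · e^B` on the modulated edges of the model's
configuration. With all B = 0 the two condition predictions are
byte-identical, which the sweep normalization relies on.

### Observation scale

At the prior gain L = 1 the neural contribution to the channel PSD is
~10⁻⁵ of the noise floor — the kernel's DC gain is T = 8 ms, so voltage
responses to unit-PSD input are tiny. The gain prior's variance of 64
exists precisely so L can absorb the unit mismatch during fitting.
Consequently: (i) the beta-power exploration reports the circuit's
spectral output without the observation-noise floor (the floor is
condition-independent and would mask every effect); (ii) the synthetic
generator produces spectra at log-gain 7.5 (L ≈ 1800, well inside the
prior), giving a beta peak ~two orders of magnitude above the noise floor
— the high-SNR regime that motivates the data log-precision prior of 12.

## Feature extraction

The raw-recording pipeline: 2nd-order Butterworth band-pass 15–35 Hz
applied forward–backward (zero-phase, so envelope timing is unbiased; the
effective magnitude response is the squared 2nd-order response), Hilbert
envelope, segmentation into non-overlapping 500 ms epochs (trailing
remainder dropped, never padded), per-epoch envelope area Σ env · dt.
Thresholds are linear-interpolation percentiles of the areas computed per
recording; epochs strictly below the 5th percentile are labelled LB,
strictly above the 95th HB, everything else (including threshold ties) is
discarded. Five epochs per condition are then drawn uniformly at random
under a seed.

Per-condition spectra are Burg autoregressive estimates (default order 16)
averaged across the selected epochs: raw periodograms of 500 ms segments
have 2 Hz resolution and high variance, while AR(16) resolves a beta peak
against a 1/f background from 500 samples. The estimator order is an
argument; order 8–24 gives materially identical condition contrasts on the
synthetic generator.

## Inversion

Variational Laplace on the feature vector y = [log g_LB(f); log g_HB(f)].
Log residuals equalize the relative misfit across a density scale spanning
orders of magnitude. The scheme alternates damped Gauss–Newton updates of
the posterior mean (Levenberg regularization λ·diag(H); a step is accepted
only if the free energy improves, so the accepted-iterate F sequence is
non-decreasing) with a 1-D Newton update of the log data precision under
its N(12, 1/32) prior. The precision update uses the posterior-expected
squared error rss + tr(J Σ Jᵀ); omitting the trace term biases the
precision upward and makes credible intervals under-cover. Optimization
starts at the prior mean (no random initialization; results are
deterministic given the data), stops when F improves by less than 10⁻³
nats over 4 consecutive accepted steps, and caps at 128 iterations with a
warning flag. Jacobians are forward finite differences (step 10⁻³ on the
log-scalings) with a backward-difference fallback at stability boundaries.
Unstable proposals are treated as rejected steps. A `fixed_precision` mode
freezes the hyperparameter for tests, and `free=` restricts optimization
to a named parameter subset (reduced models used for recovery studies).

The reported free energy is the Laplace bound: Gaussian log-likelihood of
the residuals at the posterior mean, minus the Gaussian KL divergences of
the parameter posterior and the precision posterior from their priors.

## Comparison and group stage

FFX comparison sums per-subject free energies per model; posteriors are
the softmax under uniform model priors. Family posteriors use a prior
uniform over families and uniform within each family (prior mass
1/(K·|family|) per model), which corrects for unequal family sizes; each
family's posterior is the summed posterior mass of its members.

The group stage is a multivariate random-effects model over subject
posterior means m_i with their posterior covariances S_i:
m_i = μ + b_i + e_i, b_i ~ N(0, diag(τ²)), e_i ~ N(0, S_i), estimated by
EM — group mean as the precision-weighted average with weights
(S_i + diag(τ²))⁻¹, τ² from the posterior moments of the subject effects.
This is deliberately the simplest useful form of the hierarchical
(parametric empirical Bayes) stage: one group-mean regressor, diagonal
between-subject covariance, no covariates. It reduces to the
precision-weighted fixed-effects average as τ² → 0 and is validated by
recovery on synthetic groups. By default the couplings, condition effects
and time constants are taken to the group level.

## Exploration

`sweep_beta_power` grids two condition effects over [−1, 1], clamps any
others via an explicit map, predicts the high-beta output spectrum per
cell and reports its 15–35 Hz integral (trapezoidal, on the native grid)
normalized by the low-beta baseline. The description of which connections
were varied admits two readings (sweep MP→SP with REL→RET, or sweep MP→SP
with REL→DP under weak/strong REL→RET); the axes and clamps are explicit
arguments so both are runnable, with the weak/strong scenarios realized as
clamp values −1 and +1 — the sweep range endpoints, a documented default
rather than a claim about the original values. Cells whose high-beta
linearization is unstable are flagged in a boolean mask and set to NaN,
never dropped. The all-zero cell equals 1 exactly because both conditions
then run the identical code path.

`population_spectra_report` tabulates per-population source spectra (no
channel noise, no observation gain), peak frequencies and band powers for
both conditions.

### Reference modulation pattern

Synthetic studies need one canonical "truth" for the low→high transition.
`synthetic.REFERENCE_MODULATION` strengthens MP→SP, REL→RET, REL→DP and
REL→II (+0.4) and weakens SP→MP (−0.1), RET→REL (−0.05) and the
corticothalamic projections (−0.1/−0.05). The signs follow the reported
direction of each connection's change; the magnitudes weight the
connections reported as dominant. Under this pattern every population's
beta-band output rises from LB to HB (ratios 1.2–2.5) and the channel
output rises 2.2×.

## Synthetic data

`generate_bursty_ecog` emulates the statistical structure the epoch
classifier assumes: a 1/f background plus a beta carrier (default 25 Hz)
gated by a two-state Markov process (default 0.4 bursts/s, 300 ms mean
duration, 3× background amplitude), smoothed with a 50 ms Hann window.
Ground-truth burst intervals are returned for scoring. It does not emulate
electrode artifacts, line noise, non-stationary background drift, or
burst-frequency variability — so passing classification tests show the
pipeline's correctness on clean burst statistics, not robustness to
recording pathology.

`simulate_timeseries` integrates the full nonlinear delayed circuit with
Heun's method at 0.1 ms steps (conduction delays are exact multiples of
the step; delayed voltages are read from the stored trajectory). Heun
rather than plain Euler–Maruyama because the artificial damping of a
first-order scheme at 0.1 ms is comparable to the physical damping of the
sharp beta resonance and would corrupt the oracle; the driving noise is
band-limited (synthesized in the frequency domain to match G_u exactly),
so the system is effectively a randomly driven ODE and a second-order
scheme is appropriate. A step-halving test bounds the discretization error
on band power below 5%. Trajectories cannot diverge through the recurrent
coupling — the sigmoid saturates — so the divergence guard (error naming
the blow-up time) triggers only on numerically degenerate settings.

`generate_group_dataset` draws per-subject log-scalings around a known
condition-effect pattern (between-subject sd also applied to thalamic and
extrinsic couplings), predicts both conditions, and applies multiplicative
log-normal observation noise of sd 0.0025 ≈ e^(−12/2) per frequency — the
noise level implied by the data-precision prior, so generator and
likelihood are mutually consistent. Unstable subject draws are redrawn (up
to 10, counted in the truth record). All generators are deterministic
under their seeds, and truth sidecars carry everything needed to score
downstream stages.

## Problem sizes

The validation studies run at desk scale, as the package's own choice of
test conditions: oracle cross-validation uses five random stable prior
draws with 120 s simulations; recovery uses 20 seeded replicates with
reduced (condition-effect + gain) fits; model recovery uses 5 replicates
against 6 alternative models with a 15-parameter free set; group recovery
uses 2–20 synthetic subjects. Full 144-model × many-subject comparisons
are a loop away (`enumerate_models`) but are not part of the test suite.

## Known limitations

* The first-order delay operator and the exact resolvent disagree near
  sharp resonances; stability is judged by the operator's eigenvalues,
  which at the default operating point is the conservative side, but no
  guarantee is made for arbitrary parameter regions.
* Variational-Laplace credible intervals are approximate; empirical
  coverage of the 90% intervals in the recovery study is ~87%.
* The hierarchical stage estimates a diagonal between-subject covariance
  only, and free energies are not recomputed at the group level (no
  empirical-Bayes re-inversion of subject models).
* Synthetic spectra inherit the model's own spectral family
  (model-generated data); recovery results therefore quantify the
  identifiability of the inversion, not robustness to model mismatch.
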