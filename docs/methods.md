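# Methods

## The model

`specisn` simulates excitatory/inhibitory (E/I) cortical network models in
which connection strength depends on functional similarity, and quantifies
the dynamical fingerprint of *feature-specific inhibitory stabilization*.

### Rate networks

The default dynamics are rectified-linear rate equations

    tau dr/dt = -r + ([W r + s]_+)^n,

integrated by forward Euler (`dt = 0.1`, `tau = 10` in simulation time
units; `n = 1` unless a supralinear transfer function is requested).  A
divergence guard aborts integration when any rate exceeds a configurable
ceiling (default 1e6).

### Spiking networks

Leaky integrate-and-fire neurons, `tau_m dV/dt = -V + s(t)`, solved by exact
integration of the leak per time step (`dt = 0.1` ms): the membrane decays
by `exp(-dt/tau_m)` and every presynaptic spike deflects it instantaneously
by its synaptic weight in mV.  Recurrent spikes take effect in the *next*
simulation step, which makes results independent of within-step neuron
ordering.  Threshold 20 mV, reset 0 mV, `tau_m = 20` ms.

External drive is an independent Poisson process per neuron with jump
+2 mV.  The network model itself does not fix the external statistics, so
the base rate was calibrated once — 2400 events/s puts baseline rates of
the standard 500E/500I network in the 2–10 spikes/s range typical of cortex
— and frozen as the package default.

### Connectivity

Connectivity is all-to-all and dense.  Two generative rules:

* **ring rule**: `w_ij = J (1 + m cos 2(theta_i - theta_j))` with per-block
  base weight `J` and specificity `m` in [0, 1];
* **receptive-field rule**: `w_ij = J (0.1 + m exp(eta psi_ij))` with `psi`
  the pairwise Pearson correlation of rasterized Gabor receptive fields.

Optional per-synapse multiplicative noise `zeta ~ U[0, 2]` preserves block
means and Dale signs.  Per-synapse heterogeneous specificity (`m ~ U[0,1]`)
and two realism variants (80/20 E/I with 4x inhibitory weights; broader
inhibitory specificity with a stability recalibration) are provided.

**Self-connections are kept** (the rule applies at i = j as to any other
pair).  This is deliberate: excluding autapses shifts the specific-mode
eigenvalues by `J(1+m)` per block, and because the specific-mode response
slope has the form `(1-lambda)/(1-(1-g)lambda)` — a ratio of near-cancelling
terms — a shift that looks negligible (10 → 9.9) moves the ideal slope from
-1.5 to -1.0.  Keeping autapses makes the uniform- and specific-mode
eigenvalues exactly `N J` and `N J m / 2`, so simulations line up with the
closed-form theory.  A `zero_diagonal` flag restores the exclusion.

### Receptive fields and stimuli

Gabor fields on a 200x200-pixel grid spanning 50 degrees at 4 pixels/degree:
orientation and phase uniform on [0, pi), envelope width sigma = 2.5 deg,
aspect ratio 0.5 (entering the envelope as gamma^2 y'^2, the standard Gabor;
a flag reproduces the alternative gamma y'^2 form), spatial frequency
~ Gamma(shape 2, scale 0.04) cycles/degree, centres jittered uniformly in
+/-1.25 deg.  Stimulus ensembles: fields with the same generative statistics
as the receptive fields ("RF-statistics" stimuli), or full-field gratings
with fixed (0.04 c/deg) or RF-distributed spatial frequency.  A stimulus
drives neuron j as `1 + beta * corr(stimulus, RF_j)` with beta = 0.5 for
RF-statistics stimuli and 1.0 for gratings.

### Perturbation protocols

Patterned perturbations are vectors of input offsets applied to inhibitory
neurons during the perturbation window: orientation-patterned
`gamma (sin 2 theta* - 1)` (nonpositive, as the experiments reduce input;
the nonnegative printed convention is behind a flag), similarity-patterned
`-gamma exp(kappa psi_ref)` (kappa = 2, gamma = 0.25 default), a nonspecific
uniform control on [-2 gamma, 0] (support matched to the patterned protocol
so slope comparisons are like-for-like), a shuffled control (same multiset,
random assignment), partial patterns (a fraction f of neurons retains its
value), and scaled/sign-flipped variants.

Rate experiments run a baseline window [0, 300) and a perturbation window
[300, 700) (time units), starting from the settled baseline state so window
means measure the perturbation rather than residual convergence; the first
third of each window is discarded.  Spiking experiments run paired 5 s
(configurable) windows across repetitions with independent seeds, expressing
the input offsets as scalings of each inhibitory neuron's external Poisson
rate (factor `1 + delta_s / 2`, floored at 0).

### Metrics

* **Slope metric** — OLS regression of per-neuron inhibitory response change
  on input perturbation, two-sided t-test on the slope.  Nonspecific
  paradoxical effect: mean response change opposite in sign to the mean
  perturbation.  Specific paradoxical effect: significant negative slope.
  For partial patterns the fit can be restricted to the perturbed subset
  (`perturbed_only`), since never-perturbed neurons measure network
  spillover, not a perturbation response.
* **Population PO/OSI** — windowed circular mean
  `R = sum r_j exp(2 i theta_j) / sum r_j` over excitatory neurons
  (10 ms windows, at least 5 active neurons); PO = arg(R)/2 in [0, pi),
  OSI = |R|.  The doubled angle `exp(2 i theta)` is used (the printed
  `exp(2 pi i theta)` convention, dimensionally inconsistent with an
  orientation period of pi, is behind a flag); the halving of arg(R) is
  forced by the doubling.
* **Spontaneous-transition (ST) index** — `STI = (1 - H_osi) <pop OSI>`,
  where H is the histogram (24 bins over [0, pi)) of POs of selective
  windows (OSI > 0.5) and `H_osi` its circular selectivity.  `<pop OSI>` is
  averaged over **all valid windows** (not selective windows only): with
  selective-only averaging, a nonspecific network's rare chance-selective
  windows — random POs, high OSI by construction — drive its STI as high as
  a specific network's, destroying the ordering across conditions; the
  all-window form preserves it.  The selective-only variant remains as an
  option.  A shuffle null (100 within-neuron time permutations) gives the
  bootstrapped STI (observed minus null mean).
* **Pattern-interval correlation** — mean Pearson correlation between
  E-population activity vectors at a given window separation.

### Linear-response theory

At an interior fixed point the inhibitory response to an inhibitory-input
perturbation is `delta_r_I = M delta_s` with
`M = [I - W_IE (I - W_EE)^{-1} W_EI - W_II]^{-1}` (the bracket follows from
eliminating the excitatory rates from the stationary equations).  For a
perturbation aligned with a specific eigenmode of eigenvalue `lambda` and
inhibition dominance `g`, the response collapses to the scalar slope
`(1 - lambda)/(1 - (1 - g) lambda)`, negative throughout the specific-ISN
regime (`lambda > 1`, `g > 1`).  Rank-one constructions
(`W = lambda v v^T`, inhibitory blocks `-g` times that) realize the closed
form exactly and are the package's analytic test bed.  The spectral
analysis preserves the E-to-E block while permuting the entries of the other
blocks within-block (preserving multiset, hence mean, variance and sign),
exposing the specific excitatory eigenmodes.

## Numerical behaviour worth knowing

* **Rectification-stabilized regimes.**  With `zeta` noise at the standard
  scale (N = 400–800, J per the rate-network table), the *linear* spectrum
  of the weight matrix exceeds 1 (leading eigenvalues ~1.2–1.5): the linear
  fixed point is unstable and the network is stabilized by a fraction of
  units pinned at zero rate.  Ring-rule simulations remain bounded and all
  paradoxical signatures survive, but slow modes drift at ~1e-3 between
  windows, and smaller networks can genuinely diverge (the guard raises
  `InstabilityError`).  Quantitative theory-vs-simulation checks therefore
  run with `zeta` off and small input jitter, per their interior-fixed-point
  premise.
* **RF-rule networks default to `zeta` off.**  The exponential-similarity
  structure plus `zeta` pushes the random bulk of the spectrum far enough
  past 1 that about half of the realizations escape rectification
  stabilization under stimulus drive; without `zeta`, every tested
  realization is stable and the response-similarity reference fraction is
  reproducible (0.86–0.94 across seeds).  An override restores the noise.
* **Supralinear calibration.**  The expansive gain multiplies the effective
  coupling at the operating point, so the linear-model weights produce
  runaway bump amplification for exponents n >= 2.  The nonlinear preset
  scales weights (and for n = 3 the drive) per exponent — n = 2: weights
  x0.25; n = 3: weights x0.10, `s = 1`, `gamma = 0.1` — placing the
  operating point in a stable supralinear ISN (E-only Jacobian eigenvalue
  7.3 and 2.9 respectively).  The expansive gain then *amplifies* the
  specific paradoxical effect (slopes -3.5 and -1.8 versus -0.55 at n = 1).
  n = 5 admits no ISN-capable scaling and trips the instability guard.
* **Broad-inhibition recalibration runs on the deterministic structure**
  (`zeta` off): with the noise on, the random bulk of the spectrum exceeds 1
  and no inhibitory scaling can reduce it, so the eigenvalue-based
  calibration would never terminate.
* **Closed-form slope recovery** is exact on evenly spaced ring
  orientations, where sin/cos of the doubled angle are discrete Fourier
  eigenmodes.  With random preferred orientations, finite-size crosstalk
  between modes moves the measured slope away from the closed form (e.g.
  -2.0 instead of -1.5 at N = 400) even in the exact linear response; this
  is a property of random finite networks, not an integration error.
* **Broadened inhibition is bounded.**  As inhibitory weights grow, the
  specific-mode eigenvalue tends to `lambda_EE (1 - m_broad)`; a network
  with `lambda_EE = 10` therefore requires `m_broad > 0.9` for any
  recalibration to succeed.  The variant defaults to `m_broad = 0.95`.
* **Quenched disorder and the partial-fraction trend.**  The specific effect
  of 70%-partial patterns is robust in the mean but seed-sensitive in single
  `zeta` realizations; the corresponding test pools 6 network realizations
  x 2 subset draws and fits over the perturbed subset.

## Baseline input

The rate-model baseline is `s = 2.0` with a frozen multiplicative jitter
`U[0.9, 1.1]` per neuron; this value keeps uniform-mode rates positive with
headroom in the standard networks.  Because the network attenuates the
uniform mode (gain ~1/11) but passes per-neuron jitter through at gain ~1,
the +/-10% jitter rectifies a fraction of units at baseline — a realistic
sparse-activity regime, and the reason quantitative linear-response checks
reduce the jitter.

## Desk scales used by the test suite

The test suite reruns every experiment at the scale that keeps the whole
run in a few minutes: the four-quadrant, positive/negative, partial and
realism-variant experiments at the full standard scale (N_E = N_I = 400);
the spiking replication at 500E/500I with 1.5 s windows and 10 repetitions;
the transition landscape at 10 s (quadrants) and 5 s (specificity grid);
the response-similarity reference sweep at the full standard scale
(reducing N in the RF-rule network changes its stability regime, so it is
not scaled down).  `scripts/acceptance.py` runs the full protocol
(400E/400I, 200 stimuli, every responsive reference).

## Known limitations

* No synaptic delays, refractoriness, conductance-based synapses, multiple
  inhibitory subtypes, or plasticity; connectivity is dense with no spatial
  wiring rule beyond functional similarity.
* The synthetic stimulus generator emulates the second-order statistics of
  the receptive-field ensemble only; natural images share its multi-feature
  character but not its exact statistics, so passing tests demonstrate the
  protocol's logic, not performance on any particular image corpus.
* Rate units are arbitrary; only signs, ratios and regression slopes are
  interpretable.
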