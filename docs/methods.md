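# Methods

## Lattice geometry

The microtubule is a grid of tubulin-dimer binding sites: 13
protofilaments, 8.0 nm axial repeat, and a 3-start helical rise of 12/13
nm per protofilament, so one full turn accumulates the 12-nm (1.5-dimer)
seam offset.  The cylinder is unrolled into a plane with 6.0 nm between
protofilament rows, because all downstream analyses operate in the 2D
image coordinates of a tracking experiment; no 3D or projection effects
are modelled.  Axial boundaries are absorbing (a motor stepping off the
end terminates its run); the lateral edges of the unrolled sheet reflect
(a sideways attempt off the sheet is a failed attempt).  Every occupant —
MAP7 MTBD, kinesin head pair, dynein — covers exactly one dimer site, the
simplest footprint consistent with mutually exclusive binding; a larger
MAP7 footprint can be emulated by decorating at a higher effective
concentration.  Exclusion is enforced by construction: placing an
occupant on a non-empty site raises, it is never silently ignored.

## Decoration kinetics

MAP7 binds empty sites at `k_on * c` per site and unbinds at `k_off`,
independently across sites, giving the Langmuir/Hill equilibrium
theta(c) = c^h / (c^h + K_D^h).  Only the ratio K_D = k_off/k_on = 111 nM
(full-length MAP7) is constrained by measurement; absolute exchange rates
are not, so `k_off = 1 /s` by convention and every equilibrium observable
is invariant to that choice.  The decoration module simulates the full
kinetics with an exact Gillespie algorithm (used by the titration
analyses); motor simulations draw the initial decoration directly from
the product-Bernoulli equilibrium, which is the exact stationary law of
the same kinetics.

During a motor run the decoration keeps exchanging.  Rather than evolving
every site continuously, each queried site is resampled lazily from the
two-state propagator conditioned on its last recorded state — statistically
identical for independent sites, and O(1) per query.  This matters: with a
frozen lattice the motor leaves a permanently empty wake, backward steps
into the wake always succeed, and the backward-step fraction at saturation
pins near 30% regardless of parameters.  With exchange at `k_off = 1 /s`
the wake refills in ~0.1 s at saturating MAP7, restoring realistic
direction statistics.  `live_exchange=False` recovers the frozen
(quasi-static) variant.

Constructs: `FL_MAP7` (MTBD + projection + weak tubulin-tail
association), `MTBD_only` (no projection), `dMTBD` (tails only; its
lattice binding is non-exclusive, does not block motors, and vanishes on
a subtilisin-treated lattice), `MAP7_N` (MTBD + tails, no projection),
`MAP7_C` (projection only), and a tau-chimera (tau MTBD grafted onto the
MAP7 projection; affinity assumed 150 nM — an undetermined constant, only
its qualitative behaviour is used).  The tail component is modelled as a
single bound fraction `tail_weight * c/(c + tail_kd)` with
`tail_weight = 0.5`, `tail_kd = 2 uM`: weak, saturable, and sufficient to
reproduce the qualitative assay pattern (blocked MTBD binding on
kinesin-saturated lattices, abolished tail binding after subtilisin).

## Motor runs

A single labelled motor head evolves by exact continuous-time Monte
Carlo with two bound-state channels:

* **Step attempt** at `k_step`; direction drawn from
  (p_forward, p_side, p_back).  Forward/backward displace the head by
  `step_size_sites` (2 sites = 16 nm for the hand-over-hand kinesin
  head; 1 site for dynein), sideways moves one protofilament.  An empty
  target is taken; an occupied target usually *pauses* the motor (it
  keeps its site and tries again later) and with probability
  `p_detach_block` dislodges it.  Pausing, rather than instant
  detachment, is what makes motors stall on MTBD-decorated lattices and
  makes their dissociation rate scale with ATP turnover.
* **Spontaneous detachment** at `k_detach0`.

A dislodged motor that carries the MAP7-binding stalk (K560, full-length
kinesin) on a MAP with a projection domain is caught by a nearby MAP7
molecule and enters the tethered state; a motor without that linkage
(K490, dynein) simply ends its run.  The catching MAP7 (anchor) is drawn
from the MAP7 sites within the 50-nm tether reach of the motor's
position, weighted by the entropic-spring factor `exp(-d^2 / 2 sd^2)`;
rescue after spontaneous detachment succeeds with probability equal to
the local MAP7 fraction within reach.  While tethered, rebinding attempts
fire at `k_rebind` (10 /s) against release at `k_release` (2 /s); a
rebinding attempt draws an empty site within reach of the anchor with the
same spring weighting and is recorded as a tether jump.  If no empty site
is in reach the run ends — the mechanism that starves kinesin at full
saturation.

Tether parameters are not measured quantities.  `reach_nm = 50` spans
the observed 16-64 nm displacement band; the spring width `sd_nm = 12`
and the dislodge probability `p_detach_block = 0.5` were calibrated (see
Calibration below).  A uniform draw over the whole 50-nm disk was tried
first and rejected: most of the disk lies at large axial offsets, which
caps the sideways-step fraction at ~27% at saturation, short of the
measured 35%.

**Run frequency** is `landing_rate x P(processive run)`, with
`landing_rate = k_land_basal * activity(c) * (1 + recruitment_gain *
theta_proj) * (1 - theta)`.  `theta_proj` is the MAP7 occupancy when the
motor can be recruited (zero otherwise) and `recruitment_gain = 5` is a
plausible but unmeasured recruitment strength — the biphasic shape needs
only `gain > 0`.  The completion probability is estimated by Monte Carlo:
a landed motor is processive when it accumulates 5 productive steps
(kinesin), or, for dynein, when `n_clear = 8` consecutive sites counting
the landing site are available.  That single integer is chosen so the
Langmuir IC50 of the normalized dynein frequency reproduces the measured
10 nM given K_D = 111 nM: theta at 10 nM is 10/121 = 0.0826 and
(1-0.0826)^8 = 0.50.  The simulated curve fits to IC50 ~ 8.5 nM (the
power-law survival is slightly steeper than a Langmuir), within the +/- 3
nM uncertainty of the measured value.  The dynein table is fitted
unweighted; binomial weights at the near-zero high-concentration points
otherwise dominate the fit.

**Autoinhibition.** Full-length kinesin is modelled with an active
fraction `activity0 = 0.005` at zero MAP7 that rises with lattice
occupancy, `a(c) = a0 + (1 - a0) * theta(c)` — a single-parameter stand-in
for stalk-mediated activation.  The kinesin-dynein assembly draws its
direction with `P(plus) = f_k / (f_k + f_d)` from the two run
frequencies; the kinesin arm is scaled once so that 20% of assemblies are
plus-end-directed on the undecorated lattice (the measured baseline), and
the same scale is reused at all concentrations.  With that single
calibration the model flips to ~90% plus-end at 10 nM MAP7 (93%
measured).

## Trajectories and step detection

Synthetic imaging samples the head position (piecewise constant between
binding events; tether excursions are not spatially resolved) every 0.1 s
and adds independent Gaussian localization noise of 2 nm per coordinate.
Stepping traces use the limiting-ATP preset `k_step = 1 /s`, i.e. ~1-s
dwells and ~10 frames per plateau.  Ground-truth changepoints travel in a
sidecar table (`<name>.truth.csv`), never in the analysis input.

The step finder fits each coordinate as piecewise constant by greedy
chi-square insertion: at each iteration the split with the largest
residual-sum-of-squares reduction is placed; insertion stops when the
best remaining gain falls below `penalty * sigma^2`, with sigma estimated
robustly from median absolute successive differences (so genuine steps do
not inflate it) and `penalty = 30`, calibrated to keep the false-positive
rate on flat 2-nm-noise traces below 5% while recovering >= 95% of 16-nm
steps with >= 10-frame dwells.  A coordinate-descent refinement pass then
re-optimizes each changepoint between its neighbours, which removes the
occasional one-frame misplacement of pure greedy insertion (verified
against an exact dynamic-programming segmentation in the tests).
Changepoints detected in x and y within the same inter-frame gap merge
into one 2D step event; step vectors are differences of adjacent plateau
means.

Classification resolves longitudinal classes first: BACKWARD when
dx <= -8 nm, then LARGE_JUMP when dx > 20 nm (one full step plus
tolerance — the tethered-diffusion band), then SIDEWAYS when
|dy| >= 4 nm, else FORWARD.  Longitudinal-before-lateral mirrors how
tracking studies tally longitudinal and sideways events separately; all
thresholds are exposed in `StepThresholds`.

## Calibration

Preset constants not fixed by measurement were calibrated once against
the published statistics and then frozen:

* `p_side0 = 0.096`, `p_back0 = 0.044`: chosen so the *detected*
  bare-lattice fractions are ~9% and ~3%.  The pipeline loses a few
  percent of sideways and ~30% of backward events to changepoint merging
  (a backward step followed quickly by a forward step cancels), so the
  generative probabilities must sit slightly above the observed rates.
* `p_detach_block = 0.5`, tether `sd_nm = 12`: chosen so the
  near-saturating pipeline (1000 nM, theta ~ 0.90) reproduces ~35%
  sideways and ~26% backward.  Across five seeds the frozen presets give
  8.6 +/- 0.4% / 3.1 +/- 0.1% (bare) and 36 +/- 2% / 25 +/- 2%
  (saturating), with the modal forward step at 16 nm in every replicate.

## Problem sizes and numerical choices

The shipped analyses run at desk scale: decoration titrations use a
13 x 300-site lattice (the K_D acceptance test uses 13 x 770 = 10,010
sites), run-frequency points use 200-2000 landing trials, and stepping
assays use 200 trajectories of up to 60 s at 10 Hz.  Dose-response fits
use multi-start trust-region least squares (5 log-spaced EC50/IC50
starts; the biphasic surface is multimodal), retain c = 0 points (all
models are defined there), and report covariance standard errors with a
seeded residual bootstrap as cross-check.  Degenerate inputs are flagged
rather than raised: constant responses (`non_identifiable`), monotone
data under the biphasic model (`no_biphasic_evidence`, by AIC against a
single Hill), increasing data under Langmuir (`increasing_response`).
All stochastic components accept either an integer seed or a
`numpy.random.Generator`; every shipped analysis is reproducible from a
single seed.

## What the synthetic data do and do not emulate

The generators reproduce the statistical structure the analyses rely on:
piecewise-constant stepping with exponential dwells, Gaussian
localization noise, multiplicative intensity noise with replicate
structure in titrations, and rasterized kymographs.  They do not model
photophysics (blinking, bleaching), camera noise beyond additive
Gaussian, drift, the 3D projection of the microtubule cylinder onto the
image plane, MT dynamics, GTP/GDP lattice states, cooperative MAP7-MAP7
interactions, MAP7 diffusion along the lattice, or load-dependent
stepping.  Passing tests therefore demonstrate internal consistency of
the mechanism and analysis chain at realistic noise levels — not that the
model captures every feature of real recordings.

## Known limitations

* The biphasic EC50/IC50 of kinesin run frequency depend on the
  unmeasured `recruitment_gain` and tether lifetimes; only the biphasic
  shape (interior maximum, AIC preference) is a robust prediction.
* Direction statistics at saturation are calibrated, not predicted ab
  initio; the model's content is that one obstacle-dislodge probability
  and one tether width reproduce both conditions simultaneously.
* The tug-of-war direction draw is a two-state weighting of independent
  run frequencies, not a mechanical force-balance model.
* The dynein obstacle-clearance criterion compresses unmodelled
  microtubule-gating detail into one integer (`n_clear`).
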