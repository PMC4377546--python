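# Methods

## The 1D tug-of-war model

Two processive dimeric motors of opposite directionality share a scaffold and
are coupled through a linear spring of stiffness k_s.  The inter-motor
tension T starts at zero.  Dwell times between steps are exponential with
unloaded means 170 ms (myosin V, the stronger motor) and 215 ms (myosin VI);
at each round the motor with the shorter sampled dwell steps, raising T by a
Gaussian increment with mean ΔT and standard deviation 0.1 ΔT, truncated at
zero.  Simulation is in normalized units: forces in units of the weaker
motor's stall force F_low, so the stall forces are (r_s, 1) with
r_s = F_high/F_low, and the only mechanical free parameter of the
single-filament mode is ΔT/F_low (mechanically ΔT = k_s·s for step size s;
k_s and s never enter separately).  The published stall forces (~3 pN for V,
~2 pN for VI) give the default r_s = 1.5.

**Resolution rule.**  The published step rules are ambiguous about which
motor is designated the loser when a step drives T past "the stall force of
the stepping motor".  Two readings are implemented:

* `stepper_attempt` (default): a motor loses when its *own* step raises T
  above its *own* stall force.  The race stays load-independent by default:
  the force–velocity factor 1 − T/F_stall of the stepping motor applies as a
  common factor to both motors' dwell-time distributions and therefore
  cancels exactly in an exponential race.
* `exceeded_stall`: after any step, a motor whose stall force T now exceeds
  back-steps and loses; if one step crosses both stalls the stepping motor
  loses.

The default was fixed by simulating both rules (with and without per-motor
load-dependent dwells) and comparing against the published calibration: only
`stepper_attempt` with the load-independent race reproduces the documented
correspondence between a 68% single-filament flux and ΔT/F_low = 0.55 at
r_s = 1.5, together with a monotone non-increasing flux in ΔT/F_low and
non-decreasing flux in r_s.  With per-motor load-dependent dwells
(`load_dependent_dwell=True`, available as a flag) the flux curve becomes
non-monotone and the calibration lands near 0.7; under `exceeded_stall` the
weaker motor essentially always loses below ΔT/F_low ≈ 0.7 and the
calibration is impossible.  Under the default rule the intuition is simple:
once T is within one increment of F_low, each round is a race in which the
weaker motor loses outright with probability 170/385 ≈ 0.44 (it takes the
fatal step itself); otherwise the stronger motor carries T upward until its
own step crosses r_s.  At r_s = 1.5 and ΔT/F_low ∈ (0.5, 0.75) exactly two
such races fit between the stalls, giving Φ_out ≈ 0.44·(2 − 0.44) ≈ 0.69.

**Stall handling.**  When a motor is at or beyond stall (1 − T/F ≤ 10⁻⁶),
load-dependent mode treats its dwell as infinite under `exceeded_stall`
(it can never win the race) and as an immediate loss under
`stepper_attempt` (its next move is the back-step).  Simultaneous dwell
ties — probability zero — are resolved by resampling.  Competitions are
capped at 10⁶ steps; hitting the cap (e.g. ΔT ≈ 0) raises an error rather
than returning a winner.

**Keratocyte mode.**  On a branched network the tension gained per step
depends on the lever rigidity of the stepping motor: a myosin V (rigid)
step raises T by N(ΔT_high, 0.1 ΔT_high), a myosin VI (flexible) step by
N(ΔT_low, 0.1 ΔT_low).  At ΔT_high = ΔT_low the mode is bit-identical to
the 1D mode (same code path and random stream).  The flexible motor's
increment is anchored at the single-filament calibration
(ΔT_low/F_low = 0.55) when inverting for the ratio; anchoring ΔT_high
instead was examined and makes the measured 52% network flux unreachable.

**Calibration.**  `calibrate_dT_norm` and `calibrate_dT_ratio` scan a grid
(ΔT/F_low ∈ [0.05, 1] step 0.05; ratio ∈ [1, 2.4] step 0.05; ≥5000
competitions per point), reject flat curves ("uncalibratable", e.g. matched
motors at r_s = 1, where the flux is 0.5 for every ΔT) and targets outside
the attainable range, and return the midpoint of the contiguous band of grid
points whose flux is within max(tolerance, 3 binomial SE) of the target; if
no point matches, the bracketing interval is bisected.  The band midpoint is
the honest estimator here because the flux curve has a plateau near
Φ_out ≈ 0.68 — a root in the classical sense is ill-conditioned — and the
reported uncertainty is the half-width of the matching band.

**Where the model deviates from the published regime boundaries.**  Under
the documented default rule, the acceptance script computes
Φ_out ≈ 75–77% at ΔT/F_low = 0.3 (published boundary: >80% for
ΔT/F_low < 0.5) and ≈ 55–57% at 0.75 (published: 60–80% on (0.5, 1)), and
the keratocyte-mode ratio calibrated to a 52% flux lands near 1.6 rather
than the published 1.20 ± 0.05.  No rule variant consistent with the
written step rules reproduces the published sensitivity of the network flux
to ΔT_high/ΔT_low near ratio 1.2 while simultaneously preserving the
ΔT/F_low = 0.55 calibration; the package reports the values its model
actually produces.

## Digitized actin networks

The synthetic keratocyte skeleton interlaces two families of straight
filaments at ±35° (the Arp2/3 branch angle) about the outward polarity axis,
with perpendicular line spacing of one mesh size plus one pixel
(compensating the finite rasterized filament width) and Gaussian jitter
(σ = 0.08 spacing) on the line offsets, thinned to a single-pixel skeleton.
Default pixel size is 2.4 nm (a 30-nm mesh spans 12.5 pixels and the 36-nm
step 15 pixels).  The polarity field is uniform toward the leading edge.

*Orientation field*: a 7×7 box (truncated at borders) is centred on each
skeleton pixel and the principal axis of the in-box skeleton coordinates is
taken as the filament direction (total least squares — perpendicular
residuals — so steep filaments are handled; an ordinary y-on-x regression
would fail near 90°).  Fit quality is R² = 1 − λ_min/λ_max of the local
covariance: 1 for a perfect line, 0 for an isotropic blob; pixels below 0.25
(or with fewer than 3 neighbours) are excluded.  The published 14%
excluded-pixel figure belongs to a particular TEM image and is not
reproducible without it.

*Mesh size*: twice the mean of the local maxima of the Euclidean distance
transform of the pore space (the mean inscribed-pore diameter), ignoring a
border margin.  The estimator carries a small negative bias (~1 px plus a
jitter term, about 5% at 30 nm) from measuring to pixel centres of
finite-width filaments; the generator's spacing compensation keeps
generation and estimation consistent, and scaling ratios are
estimator-independent (scaling a network by f scales the estimate by f
within ~2%).

## 2D stepping and the per-step tension change

Placement follows the published constraints: all four heads on skeleton
pixels, intra-motor head separation 36 ± 7.2 nm, inter-motor
centre-of-mass separation 65 ± 15 nm (hard windows; whether the bands are
hard or Gaussian-weighted is not documented — hard windows are used).  The
leading head of each motor is the one further along that motor's travel
direction.

A stepping motor's trailing head pivots about the lead head to a skeleton
pixel that is (a) 36 ± 7.2 nm from the lead head, (b) forward along the
motor's polarity, and (c) advances the motor's centre of mass by at most one
step size s — a hand-over-hand step cannot translocate the motor further
than its working stroke, which enforces the per-step bound ΔT ≤ k_s·s
exactly.  The 65 ± 15 nm ring is *not* re-imposed as a hard constraint
during stepping: a full 36-nm advance from any admissible placement
necessarily leaves that ring, so a hard ring would contradict the
single-filament limit ΔT = k_s·s that anchors the tension-per-step
calibration; instead the spring resists extension smoothly through the
stretch term of the site energy.

Site energies are G_i = ½k_F·|r_i − r_target|² + ½k_s·(stretch_i)², where
r_target is the unstrained post-stroke position one step size ahead of the
lead head along the local filament axis (directed by the polarity), and
stretch_i is the deviation of the post-step centre-of-mass separation from
the 65-nm rest length.  The lever term uses the full displacement from the
relaxed stroke endpoint rather than only its perpendicular component: the
lever must deform to park the head anywhere other than the stroke endpoint,
and a perpendicular-only penalty would leave all collinear candidates
degenerate, breaking both the rigid-limit saturation of ΔT at k_s·s and the
single-filament equivalence.  Sites are drawn with Boltzmann probabilities
exp(−G_i/kT)/Σ exp(−G_j/kT), kT = 4.1 pN·nm.  Empty candidate sets are
recorded as no-step events and excluded from ΔT statistics.

ΔT = k_s(Δx_post − Δx_pre) is collected over ≥400 independent
placement-plus-single-step samples per stiffness setting (defaults
k_s = 0.05 pN/nm, k_F/k_s ∈ {0.01, 0.1, 1, 10, 100}); rigid/flexible
ratios are computed on the same network with the same seed schedule.

## Trajectory analysis

Filters are strict inequalities: more than 6 frames and a maximum
displacement from the start of more than 860 nm (8 pixels at the 107.5 nm
camera pixel implied by that equivalence); net displacement rather than path
length is used where the convention is ambiguous.  Direction is classified
by the change in distance to the cell periphery measured along the local
polarity ray (ray–polygon intersection): negative change is outward.
Changes below 1 nm (far below localization noise) are tangential and the
track is excluded from flux counts.  The speed estimator is along-path
length over elapsed time; with localization noise σ it is biased upward by
roughly 2σ²/(v·Δt²) per frame, which the tests quantify against noise-free
tracks (e.g. ≈ +6 nm/s at 162 nm/s and σ = 15 nm).  Uncertainties use the
half-sample bootstrap: ≥1000 subsets of size ⌊N/2⌋ drawn without
replacement, SEM = the standard deviation of the subset means (this agrees
with the binomial closed form within a factor 1.5 for N ≥ 200).  The
flux-vs-copy-number-difference line is ordinary least squares; the pre/post
photo-cleavage comparison splits frame-to-frame speeds at the cleavage time
and uses a one-sided permutation test (10⁴ shuffles) because no test is
prescribed by convention for these small, non-Gaussian samples.

## Synthetic data generator

The generator emulates: a ~30 µm × ~10 µm elliptical lamellipodium with a
radial outward polarity field; strictly unidirectional tracks (direction
drawn once per track, Bernoulli(Φ_out)); per-track constant speed jittered
around 162 nm/s (outward) or 66 nm/s (inward) with 10% CV; 2 Hz sampling
(0.5 s frame interval); isotropic Gaussian localization noise of 15 nm,
typical of sub-pixel centroid fits of bright scaffolds; durations uniform on
5–60 s, truncated before the track reaches the cell margin.  It does *not*
emulate: curved or reversing trajectories, pausing, track fragmentation or
mis-linking, spatially varying polarity disorder, scaffold dimers, or
photophysics.  Passing parameter-recovery tests therefore demonstrates the
internal consistency of generator and pipeline, not robustness to those
real-data pathologies.

## Problem sizes and determinism

Default simulation sizes: ≥1000 (typically 2000–6000) competitions per flux
estimate, 5000–6000 per calibration evaluation, 400 steps per 2D stiffness
point on a 2 µm × 2 µm network (~60k binding sites), 1000–2000 synthetic
tracks for recovery checks.  Every stochastic function takes a NumPy
Generator or integer seed; the acceptance script derives all streams from a
single `--seed`.

## Known limitations

* The resolution-rule ambiguity is decided empirically (see above); the
  published keratocyte-mode sensitivity near ΔT_high/ΔT_low ≈ 1.2 is not
  reproduced by any variant of the written rules, and the regime boundaries
  at ΔT/F_low = 0.3 and 0.75 sit a few points below the published bounds.
* The 1D model resolves a winner, not a spatial path; run lengths, pauses
  and >2-motor ensembles are out of scope.
* The 2D engine samples single steps from fresh placements (matching the
  published ≥400-repeat procedure); it does not simulate long walks, so
  trajectory shapes on networks are out of scope.
* The mesh estimator is one of several possible pore-size definitions;
  absolute mesh values carry its documented bias, while scaling ratios do
  not.
* Real TEM skeletonization is not implemented; orientation analysis assumes
  an already-skeletal raster.
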