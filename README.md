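# myosort

Stochastic simulation and trajectory analysis of cargo sorting by
antagonistic myosin motors on actin tracks.

Myosin V and myosin VI are processive, dimeric actin motors of opposite
directionality that co-occupy membrane cargo: V walks toward the barbed
(plus) end of actin filaments, VI toward the pointed (minus) end.  When both
are coupled to one scaffold they engage in a tug of war, yet the scaffold
moves strictly unidirectionally — the competition resolves quickly, and only
the *fraction* of scaffolds moving each way (the directional flux) reflects
the underlying contest.  `myosort` implements, as a tested pipeline:

1. **A 1D tug-of-war model** (`myosort.tugofwar`).  Two motors coupled by a
   linear spring race exponential dwell times (myosin V: 170 ms mean,
   VI: 215 ms).  Each forward step raises the inter-motor tension *T* by a
   Gaussian increment N(ΔT, 0.1 ΔT), with ΔT = k_s·s for step size *s* and
   spring stiffness k_s.  A motor whose step drives *T* above its own stall
   force back-steps and loses.  In normalized units the model has two knobs:
   the stall-force ratio r_s = F_high/F_low (≈1.5 for the V/VI pair:
   ~3 pN vs ~2 pN) and the tension per step ΔT/F_low.  The outward flux
   Φ_out = n₊/(n₊+n₋) over ≥1000 competitions maps those knobs to the
   measured quantity, and `calibrate_dT_norm` / `calibrate_dT_ratio` invert
   that map against a measured flux.  A keratocyte mode assigns different
   increments ΔT_high/ΔT_low depending on which motor steps, emulating
   lever-arm rigidity differences on a branched network.
2. **Digitized actin meshworks** (`myosort.actin`): synthetic keratocyte-like
   skeletons with filaments near the ±35° Arp2/3 branch angle and ~30 nm
   mesh, per-pixel filament orientation by 7×7 total-least-squares line fits
   (R² < 0.25 excluded), geometric rescaling, and a distance-transform
   mean-pore-size estimator.
3. **2D network stepping** (`myosort.stepping`): two spring-coupled dimers
   step hand-over-hand on the skeleton; candidate sites 36 ± 7.2 nm from the
   lead head are chosen by Boltzmann weights over the deformation energy
   G_i = ½k_F·|r_i − r_target|² + ½k_s·stretch², giving the per-step tension
   change ΔT = k_s(Δx_post − Δx_pre) ≤ k_s·s as a function of lever rigidity
   k_F/k_s.
4. **Trajectory analysis** (`myosort.tracks`): motility filters (>6 frames,
   >860 nm), polarity-field direction classification via the distance to the
   cell periphery, outward flux with half-sample bootstrap SEM, speed
   estimates, the linear flux-vs-(V−VI copy number) fit, and pre/post
   photo-cleavage speed comparison.
5. **Synthetic data** (`myosort.synth`): lamellipodium-like cell geometries
   and unidirectional tracks with specified flux, speeds (162/66 nm/s),
   2 Hz sampling and localization noise — the generator's contract is that
   the analysis pipeline recovers its parameters.

## Worked example

```python
import numpy as np
from myosort import (TugOfWarParams, estimate_flux, calibrate_dT_norm,
                     generate_network, scale_network,
                     TrajectoryGenSpec, generate_geometry,
                     generate_trajectories, analyze_tracks)

# outward flux of the myosin V/VI pair at r_s = 1.5, dT/F_low = 0.55
p = TugOfWarParams(r_s=1.5, dT_norm=0.55, n_runs=5000, seed=1)
est = estimate_flux(p)
print(f"phi_out = {est.phi_out:.3f} +/- {est.sem:.3f}")

# invert the simulator against a measured single-filament flux of 68%
res = calibrate_dT_norm(0.68, r_s=1.5, n_runs=5000,
                        rng=np.random.default_rng(1))
print(f"dT/F_low = {res.value:.2f} +/- {res.uncertainty:.2f}")

# build a 30-nm-mesh keratocyte-like network and rescale it
net = generate_network(2000, 2000, mesh_size=30.0, seed=1)
print(f"mesh = {net.mesh_size:.1f} nm; "
      f"scaled x0.75 -> {scale_network(net, 0.75).mesh_size:.1f} nm")

# generate tracks at a known flux and recover it through the pipeline
geo = generate_geometry(seed=1)
tracks = generate_trajectories(
    TrajectoryGenSpec(n_tracks=500, phi_out=0.68, seed=1), geo)
s = analyze_tracks(tracks, geo, rng=np.random.default_rng(1))
print(f"recovered phi_out = {s['phi_out']:.3f} +/- {s['sem_bootstrap']:.3f}")
```

prints

```
phi_out = 0.676 +/- 0.007
dT/F_low = 0.55 +/- 0.13
mesh = 28.4 nm; scaled x0.75 -> 21.0 nm
recovered phi_out = 0.694 +/- 0.023
```

The first line says that with a tension gain of 0.55 F_low per step the
stronger motor wins about two thirds of the competitions; the second inverts
that relation — a measured 68% flux calibrates the tension per step to
ΔT/F_low ≈ 0.55 (the quoted uncertainty is the half-width of the band of
values statistically consistent with the target).  The last two lines check
the mesh generator against its own estimator and the trajectory pipeline
against the generator's ground truth.

A command-line interface mirrors these operations:

```sh
myosort simulate-1d --rs 1.5 --dt-norm 0.55 --n-runs 5000 --seed 1
myosort calibrate --target-flux 0.68 --rs 1.5 --seed 1
myosort build-network --mesh-nm 30 --seed 1 --out scratch/net
myosort synth --n-tracks 500 --phi-out 0.68 --seed 1 --out scratch/demo
myosort analyze-tracks scratch/demo_tracks.csv \
    --geometry scratch/demo_geometry.json
```

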