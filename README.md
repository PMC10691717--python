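# burstcoast

A data-driven model of schooling rummy-nose tetra (*Hemigrammus
rhodostomus*) under varying light intensity, together with the full
measurement pipeline used to calibrate and validate it.  It is aimed at
researchers in collective animal behavior who want to simulate
burst-and-coast fish schools in a circular arena, extract interaction
functions from trajectory data, and study how illumination-dependent
interaction strengths reshape collective motion.

## The model

*H. rhodostomus* swims intermittently: at each **kick** a fish picks a new
heading and then glides along a straight segment while its speed decays
quasi-exponentially with time constant τ₀.  The n-th kick of fish *i* obeys

    t_i^{n+1} = t_i^n + τ_n,
    φ_i^{n+1} = φ_i^n + δφ_i^n,
    u_i^{n+1} = u_i^n + l_n ê(φ_i^{n+1}),

with the position during the glide interpolated as
`u(t^n + Δt) = u^n + l_n [1 − e^(−Δt/τ₀)]/[1 − e^(−τ_n/τ₀)] ê(φ^{n+1})`
and `l_n = v_n τ₀ (1 − e^(−τ_n/τ₀))` linking peak speed, duration, and
length.  The heading change is an additive combination

    δφ = δφ_R + δφ_W + δφ_S,

* **spontaneous**: `δφ_R = γ_R (1 − α e^{−(r_w/l_w)²}) g`, Gaussian noise
  whose amplitude is reduced near the wall;
* **wall**: `δφ_W = γ_w e^{−(r_w/l_w)²} · O_w(θ_w)` with
  `O_w(θ_w) = 1.9612 sin θ_w [1 + 0.8 cos 2θ_w]`;
* **social**: attraction + alignment, each a decoupled product of a radial
  intensity and two angular modulations,

        δφ_Att = γ_Att (d/d_Att − 1)/(1 + (d/l_Att)²) · O_Att(ψ) · E_Att(Δφ)
        δφ_Ali = γ_Ali (d/d_Ali) e^{−(d/l_Ali)²}     · O_Ali(Δφ) · E_Ali(ψ)

  summed over the k = 2 most influential neighbors (those with the
  largest |δφ_S|).  All angular modulations are normalized so the mean of
  their square over (−π, π] is 1.

A kick is accepted only if the fish would keep a comfort distance l_c
inside the wall: `|u + (l + l_c) ê(φ + δφ)| < R` for the tank radius
R = 250 mm; otherwise the spontaneous angle, length, and duration are
resampled (uniform-heading fallback after 1000 tries).  Kick durations are
drawn as `τ = −0.5 τ̄ ln(r₁ r₂)`, resampled below a threshold; for pairs
the kick length mean is modulated by the distance to the most influential
neighbor, `F_m(d) = l_m − γ_m (d + d_m) e^{−d/l_m}`.

Collective states are quantified by the dispersion (radius of gyration)
D, the polarization `P = |Σ ê_i|/N`, the milling index
`M = |Σ sin(φ̄_i − θ̄_i)|/N` in the barycenter frame, nearest-neighbor
distances, and the per-fish wall state (r_w, θ_w).

The package also implements the inverse direction: tracker output
(frame, id, pixel coordinates at 25 Hz) is converted to tank-centered mm,
identity swaps are repaired by minimum-displacement assignment, stalls are
removed, trajectories are segmented into kicks with a Savitzky–Golay
speed filter, and the interaction functions are reconstructed by binning
heading changes against the state variables, projecting out the parity
component of each interaction, factorizing the binned array into
radial × angular parts, and fitting the analytic forms above.

## Worked example

Simulate a school of 5 fish for 200 s at the brightest packaged light
condition (50 lx) and summarize its collective state:

```
$ burstcoast simulate --n-fish 5 --light 50 --duration 200 --seed 42 --out school.csv
wrote 1 run(s) to .
$ burstcoast observables school.csv --summary school_summary.json
<r_w> = 76.3 mm   <NND> = 38.7 mm   <D> = 51.2 mm   <P> = 0.915   <M> = 0.269
```

The school stays cohesive (nearest neighbors ~39 mm apart, radius of
gyration ~51 mm in a 250 mm tank), is strongly polarized (P ≈ 0.92 — the
five fish swim in nearly the same direction), and does not mill around
the tank (M ≈ 0.27).  With 25 fish the same pipeline produces a weakly
polarized group spread along the wall that rotates around the tank.

Closing the loop from trajectories back to parameters (library API):

```python
from burstcoast.io import load_params
from burstcoast.simulator import SimulationRun, run_simulation
from burstcoast.preprocess import mirror_augment
from burstcoast.reconstruction import (bin_wall_interaction,
                                       extract_wall_product, fit_wall_params)

p = load_params(1, 50.0)                       # gamma_w=0.28, l_w=50
res = run_simulation(SimulationRun(n_fish=1, duration=20_000, seed=3, params=p))
kicks = mirror_augment(res.kicks, kind="kicks")
bins = bin_wall_interaction(kicks, min_count=50)
r, f_w, th, o_w, _ = extract_wall_product(bins)
print(fit_wall_params(r, f_w, counts=bins.count.sum(axis=1)).params)
# {'gamma_w': 0.262, 'l_w': 54.8}
```

The generating wall repulsion (intensity 0.28, range 50 mm) is recovered
within ~10% from about 40 000 simulated kicks.

Parameter files for the five light conditions (0.5–50 lx) and four group
sizes (1, 2, 5, 25) ship with the package; see
`src/burstcoast/params/schema.md` for the keys, units, and the provenance
of each value (measured anchors vs synthetic placeholders).

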