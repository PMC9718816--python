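# rloopwalk

Kinetic random-walk modelling of target recognition by the CRISPR–Cas
Cascade surveillance complex.

When Cascade finds a PAM, its crRNA starts base-pairing with the DNA
target strand, displacing the non-target strand into an R-loop that grows
and shrinks one base pair at a time.  Full-length R-loops (32 bp) lock
irreversibly; mismatches act as free-energy barriers that stall and
collapse the walk.  Because the walk is reversible and locking is not,
target discrimination is kinetic: what matters is how long it takes to
reach the locked state, not how tightly anything binds.  This package
implements that picture quantitatively, for people who model
single-molecule supercoiling or FRET-style experiments on CRISPR
effectors, or who want mechanism-based off-target estimates as a function
of mismatch placement and DNA supercoiling.

## The model

The R-loop length `n = 0..N` walks on a free-energy landscape (k_BT
units, `G_0 = 0`) built from an initiation penalty, a uniform per-bp
bias, and per-mismatch penalties:

```
G_1 − G_0 = ΔG_ini(c) + b,        ΔG_ini(c) = ΔG_ini(c0) − ln(c/c0)
G_{n+1} − G_n = b + ΔG_MM·[n+1 is a penalized mismatch]
b = ΔG_bias + τ·Δφ_bp / k_BT      (Δφ_bp = 0.515 rad/bp, k_BT = 4.114 pN·nm)
```

Rates obey detailed balance `k⁺_n/k⁻_{n+1} = e^{−(G_{n+1}−G_n)}` with a
single stepping rate `k_step` for all transitions: initiation is slowed
by `e^{−ΔG_ini}`, a mismatch puts its whole penalty on the backward step
(`k⁻_m = k_step·e^{+ΔG_MM}`), and the bias is split half onto each
direction.  Every measured quantity is then an exact first-passage or
equilibrium property of this birth–death chain: formation times are mean
first-passage times to the locked state, the coarse rates k1…k4 (or six
rates for double mismatches) combine basin dwell times with splitting
probabilities, and state occupancies are Boltzmann weights.  Default
parameters are the global-fit values `k_step = 2000 s⁻¹`,
`ΔG_ini = 8.5 k_BT`, `ΔG_bias = 0.14 k_BT/bp`, C:C penalty `6.9 k_BT`.

Beyond the predictions, the package simulates the magnetic-tweezers
measurement itself (kinetic Monte Carlo of the walk, conversion of R-loop
length to DNA extension via absorbed supercoiling, Ornstein–Uhlenbeck
bead dynamics, 120 Hz camera sampling), recovers states and rates from
such trajectories (sliding-average smoothing, Gaussian-HMM segmentation,
exponential dwell analysis, fast-transition correction), fits model
parameters globally to rate/time-vs-torque tables with profile-likelihood
intervals, analyzes zero-torque fluorescence kinetics, and generates all
of these data types synthetically with the model's exact error structure.

## Worked example

A locking-deficient target with a single C:C mismatch at position 17
(PAM-distal mismatches from 27 cut the chain at 26 bp) at −4.2 pN·nm:

```python
import rloopwalk as rw

params = rw.ModelParams()            # best-fit parameter set
target = rw.TargetSpec.single_mismatch(17, 6.9, distal_cutoff=27)

landscape = rw.build_landscape(target, params, torque=-4.2)
chain     = rw.landscape_to_rates(landscape, target, params)
basins    = rw.partition_basins(landscape, target)

rw.coarse_rates(chain, basins).labeled()
# k1 = 0.158 /s   (U -> I   formation of the intermediate)
# k2 = 0.523 /s   (I -> U   collapse to unbound)
# k3 = 0.383 /s   (I -> F*  passage over the mismatch)
# k4 = 8.77  /s   (F* -> I  collapse over the mismatch)
rw.occupancies(landscape, basins)
# {'U': 0.759, 'I': 0.231, 'F*': 0.011}
```

The same machinery gives the torque-dependent seed: a mismatch that slows
locked-R-loop formation 9.2-fold at −3.4 pN·nm is indistinguishable from
the matched target (1.2-fold) at −6.7 pN·nm, and the 10-fold seed region
shrinks from 16 bp to 6 bp between those torques:

```python
wt, mm = rw.TargetSpec.wild_type(), rw.TargetSpec.single_mismatch(17, 6.9)
rw.formation_time(mm, params, -3.4) / rw.formation_time(wt, params, -3.4)  # 9.2
rw.formation_time(mm, params, -6.7) / rw.formation_time(wt, params, -6.7)  # 1.2
scan = rw.position_scan(6.9, params, [-6.7]).values[-6.7]
rw.seed_length(scan)                                                       # 6
```

Global fitting follows the statsmodels pattern — a model built from an
observation table, a results object with uncertainties:

```python
truth   = rw.ModelParams(k_step=1900.0)
targets = {f"L{L}": rw.TargetSpec.matched(L) for L in (8, 12, 16, 20)}
design  = rw.ExperimentDesign(targets=targets, torques=(-3.5, -5.0, -6.5),
                              events_per_condition=100, seed=0)
obs   = rw.make_rate_tables(design, truth, seed=4)
obs   = obs[obs.observable == "k2"].reset_index(drop=True)
model = rw.RLoopGlobalFit(obs, targets,
                          base_params=truth.with_(k_step=500.0),
                          free=("k_step",))
res = model.fit(seed=0)
print(res.summary())
```

```
Random-walk model global fit
================================================================
observations: 12    free parameters: 1    scale: log10
objective (chi2): 16.15    nfev: 12    converged: True
----------------------------------------------------------------
parameter         estimate       std err
k_step                1925          55.6  1/s
================================================================
```

The collapse rates of R-loop intermediates spanning lengths 8–20 bp and
three torques are described by the single stepping rate
`k_step = 1925 ± 56 s⁻¹` (generating value 1900 s⁻¹; 67% profile
interval 1870–1981 s⁻¹).

A thin CLI covers the prediction surfaces and the synthetic-data
generator, e.g. `rloopwalk predict seed --torque -6.7`,
`rloopwalk predict matrix --model penalty-addition`,
`rloopwalk synth rates --design design.yml --seed 3 --out data/`.

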