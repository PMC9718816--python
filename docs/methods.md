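# Methods

## The model

R-loop formation by the Cascade effector complex is treated as a
continuous-time random walk of the crRNA–DNA hybrid length `n` on the
one-dimensional lattice `n = 0..N` (N = 32 bp for the full Cascade
protospacer).  State 0 is the unbound complex; each forward step pairs one
more crRNA base with the DNA target strand while disrupting one DNA
duplex base pair.  The free-energy landscape over `n` (in units of k_BT,
with `G_0 = 0`) is built from four ingredients:

* **Initiation.**  The first base pair costs `ΔG_ini`, shifted by the
  chemical potential of the complex: `ΔG_ini(c) = ΔG_ini(c0) − ln(c/c0)`.
  The package default is `ΔG_ini = 8.5 k_BT` at the reference
  concentration `c0 = 0.5 nM`.
* **Bias.**  Each step adds a uniform bias
  `b = ΔG_bias_intrinsic + τ·Δφ_bp/k_BT`, the sum of a torque-independent
  term (default `+0.14 k_BT/bp`, a slight uphill tilt at zero torque) and
  the mechanical work per bp done against the applied torque `τ`
  (`Δφ_bp = 0.515 rad` of DNA untwisting per bp of R-loop;
  `k_BT = 4.114 pN·nm` at 25 °C).  Negative supercoiling (negative `τ`)
  tilts the landscape downhill.
* **Mismatches.**  A mismatch at position `m` adds a penalty `ΔG_MM` to
  every state `n ≥ m`, creating a barrier step at `m` and a dynamic
  intermediate basin in front of it.  Positions 6, 12, 18, 24, 30 carry
  no penalty (the hybrid is unpaired there every 6th bp); a continuous
  PAM-distal mismatch stretch truncates the chain at its first position
  (infinite free energy) and removes locking.
* **Locking.**  On fully matching distal ends, reaching `n = N` triggers
  a conformational lock with free-energy drop `ΔG_lock`.  The locked
  state is treated as absorbing on the experimental timescale, so
  `ΔG_lock` never enters a rate; its default (10 k_BT) only positions the
  locked level in exported landscapes.

Rates follow from detailed balance,
`k⁺_n / k⁻_{n+1} = exp(−(G_{n+1} − G_n))`, with one kinetic assumption: a
single unbiased stepping rate `k_step` (default 2000 s⁻¹) for every
transition.  Initiation is slowed by the full penalty
(`k⁺_0 = k_step·e^{−ΔG_ini(c)}`); at a mismatch the forward step keeps
the plain stepping rate — the rate-limiting event is DNA base-pair
disruption — and the entire penalty accelerates the backward step
(`k⁻_m = k_step·e^{+ΔG_MM}`); the per-bp bias is split half-and-half onto
the forward and backward rates of every step, the kinetic barrier sitting
midway between lattice positions.  By default the initiation step carries
the same half-bias factor as every other forward step (`torque_on_initiation=True`);
setting the flag to False moves the full bias factor onto the collapse
rate 1→0, preserving detailed balance, for the reading in which initiation
is torque-insensitive.  The measured concentration dependence (initial
formation rate linear in `c`, all other rates unchanged) is reproduced
because the concentration term sits entirely in `ΔG_ini`.

## Predictions as first-passage quantities

Everything the single-molecule experiment reports is computed exactly on
the chain:

* **Mean first-passage times** solve the linear system
  `(−Q_TT)·T = 1` over transient microstates (dense solve; N ≤ 32).  Two
  independent backends — the closed-form nested sum for birth–death
  chains and a steady-state single-particle flux formulation in which a
  transmissive boundary reinjects the particle at the start state — agree
  with the linear solve to 1e−9 relative and are cross-checked in the
  test suite, together with Gillespie sampling (3 standard errors at 10⁴
  walks).
* **Coarse states** partition the chain at penalized mismatch positions:
  U = {0}; each bound basin runs from a barrier position to just before
  the next one, the microstate that has paid a penalty starting the next
  basin.  A basin's representative is its lowest-free-energy microstate
  (the PAM-proximal one on ties, relevant only for exactly flat basins).
* **Coarse rates**: for an interior basin with representative `r` flanked
  by neighbor representatives `a < r < b`, the dwell is
  `τ_r = MFPT(r → {a,b})` and the exit rates split it by the splitting
  probabilities, `k_{r→a} = P(a before b)/τ_r`; terminal basins use the
  single-boundary MFPT.  This reproduces the k1…k4 (three-state) and
  six-rate (four-state) conventions of the experiments.
* **Occupancies** are Boltzmann weights summed per basin and normalized
  over all microstates (max-subtracted exponentials; basins below 1e−12
  of the total weight report 0).
* **Formation time** is `MFPT(0 → N)` on a lock-competent chain.

## Virtual instrument

The magnetic-tweezers readout is emulated in two tiers.  The R-loop
length is simulated either by exact (Gillespie) event sampling or by a
fixed-step scheme (±1 bp per `Δt` with probability `k·Δt`, valid for
`Δt·k_max ≤ 0.1`); both are numba kernels with one seeded generator per
run, bit-reproducible.  The latent length maps to an equilibrium DNA
extension: an `n`-bp R-loop absorbs `n·Δφ_bp/2π` turns of supercoiling,
each worth `slope_nm_per_turn` of extension.  The slope default is
55 nm/turn, typical for kbp-scale DNA in the linear regime of the
supercoiling curve at sub-pN force; conclusions in the tests are
insensitive to it because rates derive from dwell times, not amplitudes.
The bead then relaxes toward that equilibrium as an overdamped
Ornstein–Uhlenbeck process: drift `−(κ/γ)(z − z_DNA)` and diffusion
`2(k_BT/γ)Δt` per step, with stretch stiffness `κ = 0.01 pN/nm` of the
supercoiled tether and Stokes drag `γ = 6πηR = 1.5×10⁻⁵ pN·s/nm`
(R = 800 nm, η = 10⁻³ Pa·s).  Camera output is the block average over
each 120 Hz frame.  The detection-resolution estimate
`τ = SNR²·k_BT·γ/(κΔz)²` uses its own documented κ = 1.25×10⁻³ pN/nm —
the spring constant measured from length trajectories — and gives 140 ms
(~7 Hz) for SNR 3 and Δz = 50 nm; both κ values are kept because they
parameterize different quantities.

## Trajectory analysis

The analysis chain mirrors the experimental pipeline: a 16-sample sliding
average takes the 120 Hz signal to the 7.5 Hz detection bandwidth;
segmentation into a fixed number of states (K = 2, 3, 4 for zero, one,
two internal mismatches) uses a maximum-likelihood Gaussian hidden Markov
model (hmmlearn) with seeded multi-restarts (quantile-spread and
evenly-spread mean initializations) on the standardized trace, making the
result invariant under affine rescaling; the Viterbi path is relabeled by
increasing mean extension.  The emission variance is tied across states:
the dominant noise is bead fluctuation, which is state-independent, and
untied variances let the likelihood split heavily-occupied states rather
than find rare ones.  A half-amplitude threshold segmentation is provided
as a K = 2 cross-check.  Dwell times (edge-truncated dwells excluded) are
fitted by a single exponential through the empirical survival function;
the plain mean — the exponential MLE — is reported alongside, and when
the two disagree by more than 10% the dwells are not exponential and the
mean is used, with the estimate flagged.  Exit rates are transition
fractions over the mean dwell, with `SEM = rate/√n_events`.

Transitions faster than the ~7 Hz bandwidth are partially missed, which
biases both rates of the affected pair low while approximately preserving
their ratio (the equilibrium constant across the mismatch).  The
correction procedure raises the collapse member of the pair to an
independently known reference level and scales its forward partner by the
same factor.  The package validates this on the four-state double-mismatch
target (mismatches 11 and 17), where the shallow I* basin exchanges with
I above the bandwidth: the virtual instrument under-counts I↔I*
transitions, and the correction restores the forward rate to within three
standard errors of the generating value.

## Fluorescence kinetics

Zero-torque bulk traces (donor–quencher reporting full R-loop formation)
are control-subtracted (linear interpolation bridges shifted time grids)
and fitted to `F(t) = Σᵢ Aᵢ(1 − e^{−kᵢt}) + offset`, i = 1..3, amplitudes
non-negative, rates bounded to [1e−5, 1e3] s⁻¹, from multiple log-spaced
starts; the mean formation time is `Σᵢ 1/kᵢ`.  The three-exponential form
is degenerate whenever the data contain fewer than three resolvable time
scales: a duplicated or vanishing-amplitude component leaves the curve
essentially unchanged but still adds its `1/k` to the mean time.  The fit
therefore also runs reduced one- and two-component starts, resolves
residual ties (within 5%) toward the smallest mean time, and merges
components with amplitude below 2% of the total or rates within a factor
of 3 — the standard identifiability limit of multi-exponential analysis
of saturation curves — refitting the reduced form and keeping it unless
the residual degrades by more than 15%.  On curves with three well
separated components (rate ratios ≥ 10) the cleanup never triggers and
recovery is exact to the solver tolerance.

## Global fitting

`RLoopGlobalFit` follows the statsmodels Model/Results pattern: it is
constructed from a tidy observation table (target, torque, observable
label, value, SEM) plus target specifications, predicts every observable
through the first-passage solver on chains rebuilt per condition, and
minimizes weighted least squares from multiple starts
(trust-region reflective; the stepping rate is optimized in log10).  The
default objective is on log10 of rates/times — measured collapse rates
span three orders of magnitude, and log weighting keeps fast conditions
from dominating — with SEMs propagated to the log scale
(`σ_log = SEM/(value·ln10)`); a linear-scale objective is selectable.
Torque uncertainty (±0.25 pN·nm in the experiments) is treated as
abscissa error and not propagated — a known limitation of ordinary
weighted least squares.  When `dG_MM` is free it replaces the penalty of
every penalized mismatch across targets (the experiments fit one mismatch
type at a time).  Results expose Wald standard errors from the Jacobian
and 1σ (67%) profile-likelihood intervals found by re-optimizing the
remaining parameters along each profile and locating the Δχ² = 1
crossing; open-ended profiles return one-sided intervals and are flagged,
which is also how unidentifiable parameter pairs (e.g. `k_step` and
`ΔG_ini` from formation times at a single torque) surface.

Uncertainty calibration is checked by simulation: across 50 replicate
formation-time campaigns (four single-mismatch targets plus the matched
target, four torques, 27 events per condition) the median recovered
parameters sit within one reported σ of the generating values and the
67% intervals cover the truth at rates between 50% and 85%.

## Synthetic data

The generator's defaults are the study conditions: truth parameters
`k_step = 2000 s⁻¹` (1900 s⁻¹ for the intermediate-collapse design),
`ΔG_ini = 8.5 k_BT`, C:C penalty `6.9 k_BT`, intrinsic bias
`0.14 k_BT/bp`; 27 events per condition for formation-time tables (100
for the collapse-rate design, where trajectories hold ~1000 transitions);
torques in the experimentally applied range [−7, −3] pN·nm.  Rate/time
tables perturb the exact model value by the mean of `n` exponential
dwells, reproducing the `SEM = value/√n` error structure of the
measurements; trajectories run the full virtual instrument and store the
latent basin path; fluorescence traces sample per-molecule first-passage
times by Gillespie simulation and report the cumulative fraction formed
plus Gaussian noise on a per-target grid spanning three mean formation
times, with a flat noisy no-protein control.  Every artifact records its
seed and generating parameters; regeneration is bit-identical.

What the generator does *not* emulate: camera/tracking noise beyond bead
diffusion, instrumental drift and bead loss, torque calibration error,
sequence-dependent stepping rates, and the 6-bp periodic modulation of
the landscape suggested by the hybrid's unpaired positions.  Passing
tests therefore demonstrate internal consistency of model, instrument
physics and analysis chain — not robustness to those instrument
artifacts.

## Off-target surfaces

Position scans report the relative formation time `T_MM/T_WT` for a
single mismatch at every position (excluded positions exactly 1).  The
seed length at a torque is the largest position `p` such that every
penalized position ≤ p slows formation at least 10-fold, excluded
positions extending a running seed rather than breaking it; a
count-of-positions readout is exported alongside for sensitivity.  With
the default parameter set this gives a seed of 6 bp at −6.7 pN·nm and
16 bp at −3.4 pN·nm, and at zero net bias the 10-fold region covers
essentially the whole target (the extended seed).  Double-mismatch
matrices compare the full random-walk prediction with a
penalty-addition comparator defined as the product of the two
single-mismatch fold-changes (equivalently, adding apparent free-energy
penalties); only the random walk shows the proximity effect, because a
close-packed pair deepens the first intermediate relative to the second,
draining the occupancy that feeds full R-loop formation.  The *E. coli*
torque estimate partitions superhelical density into writhe and twist
(twist fraction 0.2) and applies the twisted-polymer relation
`τ = (k_BT·p_tor/h)·2π·σ_Tw` with torsional persistence length 100 nm
and helical pitch 3.5 nm, giving −8.9 to −4.3 pN·nm for σ between −0.06
and −0.029.

## Numerical choices and problem sizes

* MFPT linear systems are dense solves (chains have ≤ 33 states);
  splitting probabilities use log-accumulated products to avoid
  overflow across large penalties.
* Fixed-step KMC enforces `Δt·k_max ≤ 0.1`; the bead integrator enforces
  `Δt ≤ 0.1·γ/κ` and defaults to `Δt = 10⁻⁴ s`.
* Validation trajectories in the tests run 400–1200 s of simulated time
  (hundreds of transitions per condition) rather than the ≥3000 s of the
  laboratory protocol, and the uncertainty-calibration study uses a
  reduced design (five targets, four torques); these sizes were chosen to
  keep the suite fast while leaving sampling error well below the
  tolerances being asserted.
* Fluorescence closure tests use a 12-bp hybrid at elevated concentration
  with weak penalties, because sampling per-molecule first-passage times
  across a 6.9 k_BT barrier at reference concentration takes ~10⁶ s of
  simulated time per molecule; the properties under test (mean-time
  tracking, position independence at zero bias) do not depend on that
  scale.
* The fast-transition validation uses `k_step = 600 s⁻¹` so that the
  I↔I* exchange straddles the detection bandwidth — the regime the
  correction was designed for; at the default stepping rate the exchange
  on this target is entirely unresolvable and no analysis could recover
  it.

## Known limitations

* Mismatch "type" enters only through its penalty value; no
  nearest-neighbor sequence thermodynamics (a 48-parameter extension the
  model's structure supports but no data here constrains).
* The coarse-rate construction assumes well-separated basins; for
  shallow barriers (< ~2 k_BT) the basin picture and the dwell-based
  rates lose meaning together.
* Profile intervals assume a unimodal objective around the optimum;
  multi-start reduces but does not eliminate the risk of a missed branch.
* The instrument model has no camera integration noise or tracking
  error; real traces are noisier than the emulation at equal bandwidth.
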