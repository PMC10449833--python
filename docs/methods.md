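# Methods

## Model

### Neurons

All neurons are adaptive exponential integrate-and-fire (AdEx) point
neurons with conductance-based synapses:

    C_m dV/dt = -g_L (V - E_L) + g_L Δ_T exp((V - V_th)/Δ_T)
                - g_e(t) (V - E_e) - g_i(t) (V - E_i) - w + I_e
    τ_w dw/dt = a (V - E_L) - w

On detection of a spike, V is reset to V_r, w jumps by b, and the
neuron is clamped at V_r for the refractory period t_r = 2 ms (w keeps
evolving during the clamp).  Four parameter sets describe pyramidal
cells (PC) and the three interneuron classes (PV, SST, VIP); see
`epsvnet.model.DEFAULT_NEURON_PARAMS`.  PV cells carry no adaptation
(a = b = 0) but keep the common spike-initiation slope factor
Δ_T = 2 mV; a genuinely adaptation-free, hard-threshold
integrate-and-fire path exists for parameter sets that omit all four
adaptation constants.

Two constants required calibration because the printed sources are
corrupt or ambiguous, and the circuit's own baseline firing rates are
the calibration anchor (in vivo spontaneous rates of ~2.5 Hz for PC
and SST and ~14 Hz for PV and VIP, which the baseline input rates were
tuned to reproduce):

* **C_m** — fixed at 190 pF for all populations (PC membrane time
  constant ≈ 9 ms).  Values of 150–2000 pF were swept once; 190 pF
  reproduces all four baseline rates simultaneously and was then
  frozen.
* **PV spike initiation** — with a hard threshold instead of the
  exponential term, PV settles at 19–22 Hz for every plausible C_m;
  with Δ_T = 2 mV it calibrates to ~13.4 Hz.  The exponential term is
  therefore kept for PV.

### Synapses

Each presynaptic spike elicits a conductance transient that
superposes additively.  Two kernels are implemented
(`NetworkConfig.synapse_kernel`):

* `"alpha"` (default): g(t) = ḡ (t/τ) exp(1 − t/τ) — rise time τ,
  peak ḡ at t = τ, total charge transfer ḡ·e·τ·(driving force).
* `"exp"`: g(t) = ḡ exp(−t/τ) with instantaneous onset.

The sub-millisecond excitatory time constants (τ_e ≈ 0.2–0.29 ms)
make the kernel choice a factor-e difference in charge per spike.
Only the alpha kernel reproduces the baseline-rate anchor — under the
exponential kernel the circuit is nearly silent for every plausible
C_m — so the alpha kernel is the calibrated default; τ is then the
rise time of the alpha function.

Numerically, both kernels are propagated exactly between events via
the two-state recursion g ← d·(g + dt·y), y ← d·y with d = e^(−dt/τ)
(y ≡ 0 for the exponential kernel); V and w advance by forward Euler
at a fixed dt = 0.1 ms.  Baseline population rates change by < 5%
when dt is reduced to 0.025 ms.  The spike-initiation exponential is
clipped above at (V−V_th)/Δ_T = 16 (overflow guard below the
detection ceiling) and dropped below (V−V_th)/Δ_T = −5, where it
contributes < 0.3 pA.  Spikes are detected at V ≥ V_th + 5Δ_T for
neurons with an exponential term (the conventional numerical
surrogate for the AdEx divergence) and at V ≥ V_th for hard-threshold
neurons.

### Network

The default circuit has 4800 neurons: 3600 PC, 480 PV, 360 SST and
360 VIP.  Every ordered pair of neurons connects independently with a
type-specific probability; autapses are excluded.  The wiring follows
the canonical neocortical interneuron motif — PC excites all four
classes; PV inhibits PC and itself; SST inhibits PC, PV and VIP and
never itself; VIP inhibits SST (strong SST↔VIP mutual coupling, no
VIP→PC/PV projection).  The connectivity table is printed with rows
indexing the *target* type; the SST→SST and VIP→VIP entries, which
list a probability but no conductance, are treated as unconnected.
Both readings were checked against the baseline anchor: the
alternatives silence SST entirely or depress VIP to ~9 Hz.

Each synaptic peak conductance is its type-specific base value scaled
by an independent LogNormal(μ=0, σ=1) draw, then clipped so that a
single EPSP (IPSP) at a −55 mV holding potential never exceeds
+0.5 mV (−2.0 mV).  The cap conductance is found by bisecting a
single-synapse simulation of the passive membrane (leak anchored at
the holding potential).  All synapses conduct with a 2 ms delay —
exactly 20 integration steps, so delivery lands on the grid without
interpolation.

### External drive (synthetic data)

Every neuron receives an independent superposition of 20 homogeneous
Poisson sources through a 50 nS excitatory synapse; the equivalent
single Poisson process at 20× the per-source rate is simulated with
exponential inter-arrival times (statistically identical for
uncorrelated homogeneous sources).  Baseline per-source rates are
(16.0, 90.0, 9.3, 12.0) Hz for (PC, PV, SST, VIP).  A stimulus adds
per-population rate offsets Δλ = (Δλ_E, Δλ_P, Δλ_S); the VIP
modulation is fixed at zero, reducing the input space to three
dimensions.  Offsets may be negative as long as the final rate is
non-negative; at the rate switch, pending arrival times are rescaled
by the memoryless property.

Across trials, Δλ is a draw from a 3-D normal distribution with mean
μ^in and covariance σ^in.  The covariance is factorised into the
pairwise covariances (σ_EP, σ_ES, σ_PS) and the signed balance ratios
σ_X/Y = ±σ_XX/σ_YY (sign = sign of the pair's covariance), optionally
under a fixed total variance σ_EE+σ_PP+σ_SS.  Candidate matrices are
screened for positive semidefiniteness (smallest eigenvalue ≥
−1e−10 × scale) and rejected otherwise; rejected cells appear as
masked entries in sweep maps.  Sampled cloud points that would push a
final rate negative are clipped to the floor (and counted) rather
than discarded, preserving the trial count.

What the generator does *not* emulate: serial correlations or
oscillatory structure in the input trains, within-trial rate
modulation, and correlations between the external sources of
different neurons.  Passing tests therefore say nothing about
oscillatory network states or within-trial variability in real data.

## Trial protocol

Each trial is 1000 ms: 250 ms preparation from a cold start (V = E_L,
w = 0, g = 0) under baseline drive, stimulus onset at 250 ms, 250 ms
settling, and the final 500 ms scored as the steady-state response
(population rate = spikes / members / window).  State is carried
across the onset; nothing is reset.  Baseline calibration uses a
variant with a 2 s scoring window after the same 250 ms transient.

## Transfer-function

The steady-state rates of all four populations are measured on a 3-D
lattice of (Δλ_E, Δλ_P, Δλ_S), by default 7×7×7 over ±8 Hz with 3
repetitions per node (distinct seeds, averaged).  Nodes with
unrealizable (negative) final input rates are carried as NaN, never
zeroed.  Off-lattice queries use SciPy's trilinear
`RegularGridInterpolator` with no extrapolation; iso-firing-rate
surfaces are extracted by rejection sampling on a refined lattice
(point sets suffice for alignment analyses and are directly
testable, unlike marching-cubes meshes).

## Variability propagation

Two routes quantify how across-trial input statistics shape the
across-trial variance of the E-population rate:

* **TF mapping** — sample an input cloud (default 10 000 points), clip
  to the rate floor and lattice hull (aborting if > 5% falls outside
  the hull), interpolate each point, and take the sample covariance of
  the outputs.
* **Full simulation** — draw one Δλ per trial, run the complete spiking
  protocol per trial, and take the sample covariance of the
  steady-state rates (the paper-scale protocol is 100 trials; the test
  suite uses 30-trial replicates with a sign-based criterion to stay
  within desk-scale runtime).

Sweeps vary one factor at a time: the cloud mean (fixed shape), the
pairwise covariances at fixed variances (default diag(1.8, 0.6, 0.6)
Hz²), or the balance ratios at fixed covariance magnitude (default
0.5 Hz²) under a fixed total variance.  Operating regimes
(PV-dominated / SST-dominated / mixed) are located by scanning the
lattice for nodes with high-PV/low-SST, high-SST/low-PV, or
intermediate output rates whose E rates match a common reference
within 20%; the unmodulated baseline state is itself PV-dominated and
serves as the default PV-dominated operating point.

## Design choices and limitations

* The engine is a single compiled kernel (numba); a scalar
  reference implementation of the same update rules lives in
  `epsvnet.model` and the test suite verifies step-for-step agreement.
  Determinism is exact given seeds: connectivity, weights, input
  arrivals and cloud draws use separate named RNG streams.
* Problem sizes in the test suite (30-trial replicates, 200–400-neuron
  degenerate circuits, coarse sweep lattices) are chosen as the
  smallest sizes at which the tested effects are statistically
  unambiguous.
* The delta-method check (∇f·σ^in·∇fᵀ) holds only in the small-noise
  regime and away from lattice-cell boundaries, where the trilinear
  interpolant's gradient is discontinuous.
* The analysis assumes an asynchronous-irregular, non-oscillatory
  operating state; in oscillatory regimes a steady-state
  transfer-function is not a sufficient description, and no such
  regime is analysed here.
* Within-trial variability (e.g. Fano-factor time courses) is out of
  scope; all variability quantities are across-trial.
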