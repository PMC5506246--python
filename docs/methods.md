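# Methods

This note documents the model equations as implemented, the numerical
choices behind them, the tuning procedures, and the limits of what the
simulations show.

## Model

### Map geometry

Both layers hold `n_neurons = 200` cells on an endpoint-inclusive
uniform grid `u_n = 5·n/199` mm, n = 0…199. The afferent (log-polar)
mapping `u_T = B_u log((r+A)/A)` with `B_u = 1.4` mm, `A = 3°` places a
target of amplitude `r`; its exact inverse `r = A(e^{u/B_u} − 1)` gives
each site's preferred amplitude and, scaled by `κ`, its efferent
minivector. The model is one-dimensional: the direction coordinate `v`
is carried in the efferent formula but always evaluated at 0, where the
vertical component vanishes identically. Whether the original network
placed neurons at cell centers or endpoints is not determined by
"uniformly distributed"; the endpoint convention was chosen because it
makes both poles (0° and ~104°) exactly representable, and it is
exposed through `MapConstants`.

"Optimal" (preferred-amplitude) trials snap the requested amplitude to
the nearest grid-representable value (`snap_amplitude`); at 200 neurons
the snap is ≤ 0.3° anywhere on the map. The central neuron of a trial
is the cell nearest the target's image point, ties broken rostrally.

### Neurons

All cells are adaptive exponential integrate-and-fire (AdEx) units.
Parameters (units pF, nS, mV, ms, pA — mutually consistent, so the
update has no conversion factors):

| parameter | input layer (FEF) | SC layer |
|---|---|---|
| C (pF) | 50 | 280 |
| g_L (nS) | 2 | 10 |
| E_L (mV) | −70 | −70 |
| V_T (mV) | −50 | −50 |
| V_peak (mV) | −30 | −30 |
| η (mV) | 2 | 2 |
| a (nS) | 0 | 4 |
| b (pA) | 60 | 80 |
| V_r (mV) | −55 | −45 |
| τ_q (ms) | 30 | 10–80, site-dependent |

The SC reset potential lies *above* the spike-initiation threshold
(V_r = −45 > V_T = −50): after each reset the exponential term
immediately re-depolarizes the cell, so bursts are intrinsic and end
only when the spike-triggered adaptation `q` (jump `b` per spike, decay
`τ_q`) outweighs the synaptic drive. This knife-edge regime is what
makes burst durations and rates tunable by (τ_q, w), and it also makes
the *last* spikes of a burst extremely parameter-sensitive (see
"Numerical behavior" below).

### Input and synapses

The input layer receives the separable current
`I_ext = I_0 · exp(−(u_n−u_T)²/2σ_pop²) · t^γ e^{−βt}` with
σ_pop = 0.5 mm, β = 0.03 /ms, γ = 1.8, I_0 = 3 pA, time in
milliseconds (the temporal factor then peaks at γ/β = 60 ms and decays
below 1% of peak by 350 ms, consistent with burst durations of tens of
ms). Input cells receive no synapses; SC cells receive
`I_syn = g_exc(E_e − V) + g_inh(E_i − V)` with E_e = 0 mV,
E_i = −80 mV. Conductances jump by the synaptic strength per
presynaptic spike — the delta-function reading of the conductance ODE,
matching "increase instantly by the synaptic strength" — and decay
exponentially with τ_e = 5 ms, τ_i = 10 ms. Feedforward projections
are one-to-one with site-dependent strength `w_ff(u)`; lateral SC→SC
projections are difference-of-Gaussians (excitation 160 pS, 0.4 mm;
inhibition 50 pS, 1.2 mm; zero diagonal). The soft-WTA shape
constraints (w̄_exc > w̄_inh, σ_inh > σ_exc) are enforced when loading a
configuration file, but the library accepts any nonnegative strengths so
the strong-inhibition regime can be characterized.

### Integration scheme

Forward Euler at dt = 0.01 ms (the step size of the original
simulations; the scheme is the convention of time-driven spiking-network
simulators). State updates first, then the threshold test, then the
reset, all within the step; spikes are delivered to their targets at the
*next* step (one-step axonal delay — the minimal causal convention,
since the original work does not specify same-step recurrence).
Conductance decay uses the exact factor `exp(−dt/τ)` rather than an
Euler step, removing one discretization error that has a closed form.
Initial conditions are rest (V = E_L, q = 0, conductances 0) — the only
neutral choice. The exponential argument is clamped at
`(V_peak − V_T)/η + 5`; any state beyond V_peak fires regardless, so the
clamp cannot alter spike times at this dt. A runaway guard aborts any
trial in which a neuron exceeds 200 spikes (unbalanced lateral
excitation). Default trial horizon: 300 ms, by which the input has
decayed to < 1% of peak and all bursts are complete.

## Tuning procedures

### Single-neuron brute force

A single SC-preset neuron is driven through an excitatory synapse by
the reference input-layer train — the spike train of the most active
input cell, which by translation invariance of the drive is the
on-center response (34 spikes between ~16 and ~192 ms at the default
parameters). The default grid is 36 τ_q values × 45 w values over
[10, 80] ms × [5, 16] nS; all 1620 points integrate in one vectorized
pass. Grid points firing exactly 20 spikes (the average burst count of
recorded saccade-related cells) form the iso-count contour; a
least-squares quadratic `w(τ_q)` is fitted through them. τ_q is then
assigned linearly along the map from 80 ms (rostral) to 10 ms (caudal)
and `w_ff = quadratic(τ_q)` follows, decreasing from ~15.2 to ~6.4 nS.

### Lateral-weight search

The elitist genetic algorithm evolves integer (w̄_exc, w̄_inh) pairs in
pS: population 10, 2 elites, 8 children per generation from distinct
parent pairs drawn from the 6 best, single-point crossover on the
concatenated 8-digit decimal encoding (4 digits per weight — one
concrete realization of a "modular representation"), 5% per-digit
mutation, initial candidates uniform on [10, 500]² pS, stop when the two
top-ranked candidates repeat across generations (hard cap 50). Fitness
is the weighted RMSE sum
`0.1·RMSE(F_peaks) + 10·RMSE(spike counts) + 1000·RMSE(1 − r̂)`
over seven amplitudes r = [2, 5, 9, 14, 20, 27, 35]°, where peak rates
are compared with `F_peak(r) = F_0/√(1+βr)` (F_0 = 800 spikes/s,
β = 0.07 per degree — the printed unit "ms/°" is dimensionally
inconsistent with the formula, so per-degree is used), spike counts
with the 20-spike target, and r̂ are the central-vs-recruited burst
cross-correlations. Unstable or silent candidates score infinity. The
search machinery takes its fitness function as a callable, so it can be
exercised with cheap surrogates; the published weight pair (160, 50) pS
is used as the default without rerunning the search.

### Burst analysis conventions

Spike densities are sums of unit-mass Gaussians evaluated on a 0.5-ms
grid (finer than any kernel in use); kernel widths follow the analysis
at hand — 5 ms for cross-correlations, 8 ms for peak firing rates, 3 ms
for burst-shape comparisons. Burst onset (t = 0) is the cell's first
spike; saccade onset is the central cell's first spike.
Cross-correlations are peak-normalized inner products over the window
−10…+40 ms around saccade onset, computed on the density grid (the
original does not say whether the sum runs on densities or binned
counts), restricted to active cells within 0.65 mm of the center.

### Decoding

SC spikes are accumulated into a step function of minivector
contributions, linearly interpolated onto a 1-ms grid, and smoothed with
a Savitzky–Golay filter (window 15 ms, order 3 — unstated in the
original; the window must exceed the central ISI but stay well below
the burst duration, and nearby choices give equivalent kinematics); the
same filter's first derivative gives eye velocity. `κ` is calibrated so
the decoded 21° endpoint is exact, separately for every network
configuration (the reading of "for any network configuration …
calibrated for 21° saccade"); since the endpoint is linear in κ,
calibration is a single division. With 200 neurons and ~800 population
spikes the calibrated κ is ~1.2×10⁻³ deg/spike-weight; the literature
bound κ ≲ 10⁻⁶ presumes the real collicular neuron density and scales
inversely with population spike count. Saccade offset (for the reported
duration only) is the first post-peak drop of velocity below 5% of its
peak.

## Numerical behavior and known limitations

**Discrete-count jitter.** Because bursts terminate on a knife edge,
the spike count at fixed τ_q is not a clean staircase in w: marginal
late-burst spikes flip with ±1–2 jitter at 0.02 nS resolution, so the
20-count level set has sub-grid holes. Consequently no quadratic can
yield *exactly* 20 spikes at every contour column (verified by a
max-margin feasibility search); re-simulating at fitted pairs gives a
modal count of exactly 20 with all pairs within ±2. The same jitter
propagates to the network, whose central-cell counts vary
non-systematically between 20 and 23 across the map — the behavior the
model is meant to produce.

**Euler convergence.** Early spike times converge at first order in dt
(first-spike shift < 0.05 ms when halving dt from 0.01 ms). Late-burst
spike times accumulate timing drift across resets (ms-scale over a
34-spike train), and marginal final spikes can appear or vanish under
refinement at some parameter sets; counts and early-burst timing are
the dt-robust observables, and the tests assert exactly those.

**Characterization scan.** The peak-velocity-ratio scan over lateral
inhibitory strengths (excitation fixed at 160 pS / 0.4 mm,
σ_inh = 1.2 mm) peaks in the 50–70 pS band with per-condition κ
recalibration. In the very strong inhibition regime (≥ 200 pS) the
recruited population shrinks and κ recalibration amplifies the early
synchronous volley, so the ratio in this implementation does not drop
below 1 at σ_inh = 1.2 mm; the slow, long-tailed movements expected
there appear in the velocity *profiles* rather than the peak ratio.

**Scope.** The model is deterministic and one-dimensional: no trial
variability, no direction coding (2-D map), no multiple targets, no
oculomotor-plant or brainstem feedback dynamics, no synaptic delays
beyond the integration step, and no claim about real neural recordings
beyond the printed summary statistics used as tuning targets. Passing
tests show that the implemented equations reproduce the published
network's emergent numbers under the published parameters, not that the
biological SC works this way.

## Default problem sizes

All shipped analyses use the full 200-neuron map at dt = 0.01 ms over
300-ms trials: the tuning grid (1620 single-neuron integrations, one
vectorized pass), a seven-amplitude survey spanning 3–63°, the
three-population (5/15/25°) lateral on/off comparison, and an
eight-point inhibitory-strength scan — about forty full network trials
in total for the complete reproduction script, under a minute on one
CPU.
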