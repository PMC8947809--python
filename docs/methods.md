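# Methods

This note documents the models, numerical choices and protocols the
package implements, the defaults it ships, and what its synthetic tests
do and do not establish.

## Neuron and synapse models

**Current-based (CUBA).** Membrane: C_m du/dt = g_l(E_l − u) + I(t), with
I(t) the sum of a constant injected current and an exponentially decaying
synaptic current that jumps by the synaptic weight (nA) at each (delayed)
presynaptic spike arrival. Reference parameters: C_m = 200 pF,
g_l = 2000 nS (τ_m = 0.1 ms, emulating the high-conductance regime),
E_l = v_th = −50 mV, v_reset = −55.1 mV, τ_ref = τ_s = 10 ms.

**Conductance-based (COBA).** C_m du/dt = −g_l(u−E_l) − g_exc(u−E_exc)
− g_inh(u−E_inh) with exponential conductances (nS). Reference
parameters: C_m = 250 pF, g_l = 25 nS, E_l = v_reset = −65 mV,
v_th = −50 mV, E_exc = 0, E_inh = −80 mV, τ_exc = 2 ms, τ_inh = 3 ms,
τ_ref = 3 ms.

**Integration.** Synaptic states decay exactly per step; jumps are
applied at step start. The CUBA membrane is advanced with the exact
solution of the linear ODE driven by the exponentially decaying current
(including the degenerate τ_s = τ_m branch); the COBA membrane uses
exponential Euler with conductances held at their post-jump values over
the step. Both schemes are unconditionally stable, so the resolution
warning is tied to the synaptic/refractory time constants, not τ_m.
Defaults: dt = 0.1 ms (CUBA), 0.05 ms (COBA).

**Spiking.** A spike is stamped when the end-of-step membrane potential
strictly exceeds v_th (a strict crossing: the degenerate fixed point
u = E_l = v_th of the reference CUBA neuron does not fire). The membrane
is then clamped to v_reset for exactly τ_ref while synaptic variables
keep integrating; no sub-step threshold interpolation is used. Delays
must be multiples of dt; a zero delay delivers at the next step.

**Background.** Each neuron has one aggregate excitatory and one
aggregate inhibitory Poisson source; per step the event count is drawn
from a Poisson law with mean ν(t)·dt, independently across neurons, with
the rate schedule shared. Identical (network, duration, dt, seed)
produce bit-identical rasters.

**Validation.** The closed-form free-membrane moments (mean, variance,
effective time constant) agree with threshold-free simulations to ≲1%,
and an independent brute-force Euler integrator at dt = 0.01 ms
reproduces the kernel's activation probabilities.

## Calibration and temperature

The activation of a sampling neuron is p(z=1 | I_in) = ν_out·τ_ref,
estimated from 20 s simulations per current and fitted with the logistic
1/(1+exp(−β(I−I₀))). Because the sigmoid's location varies strongly
across backgrounds, measurement is two-stage: a coarse 25-point scan
(4 s/point) centered on the mean-matching current locates the curve, and
the final grid spans I₀ ± 2.5/β with 15 points. At the reference
background (2/2 kHz, ±0.5 nA) the fit gives β ≈ 0.72 /nA and
I₀ ≈ −1.33 nA; the logistic *scale* 1/β ≈ 1.38 nA and the midpoint
magnitude ≈ 1.33 nA are the two constants quoted in reports, and the
measured slope agrees with the Gaussian-CDF approximation
β ≈ 4 g_l/(√(2π) σ_u) evaluated from the closed-form σ_u.

**Balance line.** β and I₀ are fitted on a rate grid (default 6×6 over
0.5–12 kHz), the I₀ surface is interpolated bilinearly, the iso-offset
contour through the reference rates is extracted by marching squares,
and ν_inh = ν₀ + m·ν_exc is fitted along it (typical result m ≈ 1.05,
ν₀ ≈ −0.1 kHz, r² > 0.999). Along this line I₀ is constant and the
temperature is T = √((ν_exc+ν_inh)/(ν_exc,ref+ν_inh,ref)) — the square
root follows from Var[u] being linear in the rates; rescaling ν → s·ν
with w → w/√s leaves T unchanged.

**Boltzmann → LIF translation.** Bias currents are I_k = B_k/β + I₀
exactly. Weights are w_kj = (W_kj/β)·(τ_ref/τ_s): a presynaptic unit
that stays ON fires regularly at 1/τ_ref, its exponential PSCs
accumulate into a sawtooth with steady-state mean w·τ_s/τ_ref, and that
mean current is matched to the intended activation shift W/β. Matching a
single isolated PSC's average instead overdrives sustained interactions
by ~60%. The translation is validated behaviorally: measured pairwise
couplings are within ~5–15% of target for |W| ≲ 1 (mildly supralinear
for strong excitation), a two-unit W = 1 network samples its target with
DKL ≈ 0.002 nats, and random 4-unit networks reach ≈ 5·10⁻⁴ nats after
1000 s.

## Escape-rate fitting

The stochastic neuron shares the COBA membrane, reset and refractoriness
but fires with intensity ρ(u) = exp((u−u_T)/T)/Δt (per-step probability
1 − e^{−ρΔt}, clamped at 1). Fitting protocol per repeat:

1. Drive the deterministic LIF neuron for 100 s (default) with a fresh
   stimulus — 100 Poisson inputs at 5 Hz, 80% excitatory, weights
   uniform in [0, w_stim,max] — plus the scenario background; record
   spikes.
2. Integrate, on the same pass, a passive threshold-free twin driven by
   the **stimulus only**, reset to v_reset at every spike of the driven
   neuron and held there for τ_ref. The background is deliberately
   withheld from the twin: it is exactly the variability the escape rate
   is meant to absorb, and a twin that shares the background realization
   measures only a refractory-divergence artifact (the fitted T then
   *decreases* with background strength).
3. Histogram the twin potential at armed (non-refractory) steps and at
   spike steps in 0.5 mV bins; their ratio estimates p(spike|u). Bins
   with fewer than 10 samples, empty bins, and bins above the
   probability peak (where estimates degrade) are excluded.
4. Regress log(−log(1−p)) on u: slope = 1/T, intercept = −u_T/T.

Applied to data generated by a known escape-rate neuron (stimulus only),
the protocol recovers T and u_T to ~2% at 100 s. Applied to the
deterministic neuron, the fitted T rises monotonically with the
background scaling α in all four scenarios and follows T = c·√α
(R² ≈ 0.98 in the unbalanced-mean scenario).

**M_d.** Fit quality is the normalized intensity overlap
M_d = 2∫ν_LIF ν_fit / (∫ν_LIF² + ∫ν_fit²) on a fresh 1 s stimulus:
100 LIF trials (independent background) versus 100 escape-model trials
(no background; escape noise replaces it), intensities smoothed with a
5 ms Gaussian kernel (configurable, reported with results).

## Background scenarios

Rates scale as ν_x = α·ν_x,1 + ν_x,0 over α ∈ [0.5, 5]. Presets:
unbalanced mean (5α/5α kHz at 0.5/0.5 nS), mean balanced at −55 mV
(ν_inh from the conductance-balance relation, α ≥ 1), high variance
(5α/5α at 2.5/3.75 nS), and low excitation (1α/5α at 1/0.375 nS — the
inhibitory weight is corrected from a misprinted 3.75; see the preset
file comment — giving a near-constant mean with variance increasing in
α, the scenario's defining behavior).

## Task circuits

All four tasks are seeded, reproducible from (config, seed) alone, and
fully overridable.

**Entropy demo.** A random 4-unit Boltzmann machine (Ŵ, B ~ N(0, 0.5),
W symmetrized, biases 3 and 4 pinned to ±1) is translated into a CUBA
network; the background oscillates along the balance line
(ν_exc 0.25→10 kHz, 1 Hz). Phase-binned refractory-state readouts give
the sampled entropy, compared with the exact entropy at the
instantaneous temperature; the divergence to the T = 1 target is
smallest near the T = 1 crossings, with a small lag from the 10 ms
relaxation constants.

**WTA demo.** Four COBA neurons with bias currents (40, 60, 80, 40) pA,
lateral inhibition 3·w_stim,max, and one shared 75 Hz stimulus neuron at
w_stim,max (a shared train makes the biases decide the race; see the
design notes). Mode probabilities are the one-hot 10 ms-window states;
their entropy rises with α in every scenario (weakly in the
high-variance scenario, where the background already dominates).

**Disambiguation.** 27 COBA neurons: 3 WTA groups × 3 assemblies × 3
neurons; within-assembly excitation 8.5 nS (2 ms delay), within-group
all-pairs inhibition 17 nS (0.1 ms), and cross-group links between
same-interpretation assemblies: each assembly's neuron 0 links to the
next group and neuron 1 to the previous group, bidirectionally at 17 nS
(the printed wiring is under-specified; the adjacency is config-visible).
Background: unbalanced-mean rates, w_exc = 0.5 nS, w_inh = 0.675 nS,
α(t) ∈ [0.5, 5] at 10 Hz; each neuron receives 350 pA; biased assemblies
receive 40 pA extra (a conductance-bias mode is available but saturates
the circuit). Operating point ≈ 17–18 Hz. The background-weight tuning
scan minimizes the *relative* variance (CV²) of the mean rate across
constant background levels α ∈ {0.5, 2.5, 5} — the criterion under which
oscillating and constant background can be compared fairly. The relative
measure matters: sufficient inhibition silences the network at every
level, which trivially minimizes any absolute variance (temporal or
across levels) but maximizes the relative one. Default scan: ratio 0.5–2
in steps of 0.05, 2 runs × 10 s per level; the grid argmin is reported.

**Flickering.** Two assemblies of 20 COBA neurons; within-assembly
excitation with probability 0.1 per ordered pair (2.5 nS, delays uniform
in [1, 3] ms rounded to the grid), cross-assembly inhibition with
probability 0.5 (5 nS, 0.1 ms); assembly 1 gets a 10 pA bias; background
oscillates at 8 Hz. The mean conductance ratio E[g_inh/g_exc] ∈
[0.75, 3] is set via the inhibitory background weight
(w_inh = r·w_exc·τ_exc/τ_inh); the injected current is interpolated
linearly from 40 pA at r = 0.75 to 880 pA at r = 3 (the source prints
these currents in nS; currents are pA). Per ratio the phase profile of
the network rate (24 bins over the background phase, phase 0 at the
input minimum) yields a high-minus-low half-cycle contrast whose sign
flip locates the regime transition (≈ 1.8–1.9 with 5 × 20 s runs);
mixed states (both assemblies > 20% active in a 10 ms window) are
reported by phase after re-anchoring phase 0 to the network rate
minimum.

## Readout and metrics

States are read on a 1 ms grid by default (decoupled from dt to bound
memory). Refractory readout sets z = 1 on [t_spike, t_spike+τ_ref);
windowed readout sets z = 1 if the neuron spiked within the trailing
window (boundary inclusive). Integer state codes use neuron 0 as the
least significant bit. Mode durations exclude the final censored
interval and flag constant traces; solution detection requires the
linked assemblies strictly above 50% activity and all others at or
below it (ties count as no solution). The ISL uses the binary kernel
density with γ = 0.95, evaluated in log space via Hamming distances;
autocorrelation summaries report the Pearson coefficient by lag and its
trapezoidal area.

## Synthetic data and scope

The binary fixture generator (uniform prototypes with i.i.d. bit flips)
and the exactly enumerable Boltzmann models define the test conditions.
They emulate multimodal binary data and small sampling targets, not the
statistics of natural images or in vivo recordings: passing tests show
that the calibration, tempering and metric machinery is correct at desk
scale, not that a particular biological network samples. Training of
hierarchical generative networks and their image datasets are out of
scope; the tempering and mixing machinery is exercised on small
user-specified models instead.

## Default problem sizes

Reference calibration: 15 currents × 20 s. Balance line: 6×6 grid,
15 s/point. Disambiguation statistics: 3 × 20 s; weight scan 31 ratios
× 3 levels × 2 × 10 s. Escape fits: 3 repeats × 50–100 s, M_d from
2 × 100 × 1 s trials. Flickering: 7 ratios × 5 × 20 s. Sampling DKL:
1000 s (10⁵ refractory periods). These sizes give sampling errors
comfortably below the tolerances asserted in the test suite; all are
config arguments.

## Known limitations

- The Boltzmann→LIF weight translation is linear; strong couplings
  (|W| ≳ 2) are realized supralinearly by the exponential-PSC dynamics,
  so deep-mode fixtures are qualitatively, not quantitatively, tempered.
- COBA sampling is biased in general; temperature there is an effective
  quantity defined through the escape-rate fit, not an exact Boltzmann
  temperature.
- The escape model's single (T, u_T) pair cannot capture strongly
  bimodal conditional statistics (high-variance scenario at large α),
  where M_d degrades, as expected.
- Balance-line extrapolation below ν_exc ≈ 0.1 kHz clips negative
  inhibitory rates to zero with a logged warning.
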