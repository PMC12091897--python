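# Methods

## Model

The neuron is the reduced two-compartment Pinsky–Rinzel (PR) model of a
CA3 pyramidal cell. The somatic compartment carries a leak, a fast sodium
current `INa = gNa m∞(Vs)² h (Vs − VNa)` with instantaneous activation,
and a delayed-rectifier potassium current `IKDR = gKDR n (Vs − VK)`. The
dendritic compartment carries a leak, a calcium current
`ICa = gCa s² (Vd − VCa)`, a fast calcium-gated potassium current
`IKC = gKC c χ(Ca) (Vd − VK)` with `χ(Ca) = min(Ca/250, 1)`, and a slow
afterhyperpolarization current `IKAHP = gKAHP q (Vd − VK)` whose gate `q`
is driven by the calcium variable (`αq = min(2·10⁻⁵ Ca, 0.01)`,
`βq = 0.001`). Calcium integrates the (inward, negative) calcium current:
`Ċa = −0.13 ICa − 0.075 Ca`, so `Ca ≥ 0` is invariant. The compartments
exchange current through `gc (Vd − Vs)/p` on the soma side and the
opposite-signed `gc (Vs − Vd)/(1 − p)` on the dendrite side (`p = 0.5` is
the somatic area fraction; the absolute membrane area never enters).
Voltages use the original PR shifted convention (`VL = 0` mV,
`VNa = 120`, `VCa = 140`, `VK = −15`); rest sits a few mV below zero.
Units are mV, ms, µA/cm², mS/cm², µF/cm² — a consistent set with no
hidden conversion factors.

Rate functions are the PR originals. Four of them have removable
singularities (`αm` at 13.1 mV, `βm` at 40.1 mV, `αn` at 35.1 mV, `βs` at
51.1 mV); within 10⁻⁷ mV of the singular voltage the implementation
substitutes the analytic limit. The `c`-gate rates are piecewise at
`Vd = 50` mV; as published, `βc` dips marginally negative (≈ −3·10⁻⁴/ms)
just below the branch point, which is retained rather than clamped. The
sodium activation `m` is instantaneous (`m∞ = αm/(αm+βm)`), so the state
is 8-dimensional: `(Vs, Vd, h, n, s, c, q, Ca)`.

One deliberate parameter correction: the dendritic calcium conductance
defaults to `gCa = 10` mS/cm² (the classic PR value). The source table
this package reproduces prints 2.1 — identical digits to `gc` and almost
certainly a copy slip: with `gCa = 2.1` the dendrite cannot regenerate
calcium spikes and the model shows no bursting at any `(gc, VK)`, while
every firing pattern the study reports (and this package's tests assert)
requires the bursting backbone that `gCa = 10` restores.

## The DC field coupling

A DC induced electric field of amplitude `A` polarizes the membrane by a
constant `ΔV = Ve = A`; because `ΔV` is constant, the capacitive current
it would inject is zero. The polarization is felt by the ion channels as
an offset in the electromotive driving force, so every ionic current is
evaluated at the shifted voltage (`Vs + Ve` or `Vd + Ve`). Two terms are
deliberately *not* shifted:

- the gating kinetics, including `m∞`, which follow the bare membrane
  potential; and
- the coupling current and injected currents, which depend only on
  voltage differences or constants.

This placement is forced by an identity: if the shift entered every
voltage-dependent term, `W = V + Ve` would satisfy the unshifted
equations, making the field a pure relabeling with no dynamical effect —
incompatible with any field-dependent regime change. Shifting the driving
forces only breaks the symmetry and quantitatively reproduces the
reported sensitivity windows; shifting `m∞` as well collapses them (the
window at `gc = 1` shrinks from [−16, 11] to [−9, 14] mV). With `Ve = 0`
the model is exactly standard PR, which the test suite asserts on
randomized states against an independently written field-free derivative.

Sign convention: positive `Ve` adds a depolarizing offset to the driving
forces, which *reduces* net excitability in this model (the steady K⁺ and
leak outward currents grow faster than INa recovers); firing therefore
accelerates toward negative `Ve` until depolarization block, and slows
toward positive `Ve` until rest.

## Integration

Fixed-step classical RK4 (`k₂`, `k₃` at half-increment, `k₄` at full), the
system being autonomous. Defaults `Δt = 0.1` ms, `T = 7000` ms (70 000
steps), recording every step, from the fixed initial state
`(8.22594…, 11.28735…, 0.65710…, 0.05758…, 0.05866…, 0.03287…, 0.46175…,
46.95585…)`, a point near the firing attractor. The inner loop is
numba-compiled; results are bit-identical across runs and machines
honoring IEEE-754 double arithmetic.

Divergence. For `gc ≳ 20` mS/cm² the RK4 iteration at `Δt = 0.1` ms is
unstable through the spike upstroke and the state reaches `inf` within the
first second (at `Δt ≤ 0.05` ms the same configuration integrates cleanly
to sustained ~4 Hz spiking, so this is a step-size artifact, not a model
property). `simulate()` raises `DivergenceError` naming the failure time;
clamping is never used, since a silently clamped trajectory would corrupt
regime classification. Scans (and the acceptance script) instead request
`on_divergence="truncate"`: the valid prefix is kept, and a run that dies
before the analysis window opens contributes zero countable spikes
(F = 0, regime marker `divergent`, never *sensitive*). Under the
prescribed `Δt = 0.1` ms protocol the strong-coupling configurations
therefore report F = 0 — which is also how the study's own "firing stops
above gc = 20" number arises.

Convergence. Halving `Δt` to 0.05 ms leaves every spike *count* in the
default bursting configuration unchanged, but individual spike times drift
by up to ~4 ms by the end of the 5 s analysis window — ordinary phase
drift of a ~420 ms limit cycle, not a stability problem. A stricter
sub-millisecond spike-time agreement holds only over the first second
after the transient.

## Spike detection and regime classification

The study quantifies firing by a mean rate F without stating detection
conventions, so they are explicit here and configurable
(`ClassifierCriteria`):

- **Spike**: upward crossing of `Vs` through `spike_threshold = 20` mV
  (subthreshold activity stays below ~15 mV in this voltage convention,
  spikes overshoot to +70…+130 mV), linearly interpolated between samples,
  counted after `transient_discard = 2000` ms. F = count / window.
- **Burst**: spikes closer than `intra_burst_isi_max = 25` ms (intra-burst
  intervals are a few ms, inter-burst intervals 60–400 ms, so any cut
  between is stable).
- **No-spike traces**: judged on the final `tail_window = 2000` ms so
  decaying transients do not masquerade as sustained activity. A tail
  that still oscillates (≥ 3 peaks of ≥ 0.5 mV prominence, or standard
  deviation ≥ `resting_std_max = 0.5` mV) is a *subthreshold oscillation*,
  or a *biphasic oscillation* if it swings beyond ±`block_voltage_min`/2
  on both sides. A quiescent tail is *depolarization block* if the trace
  dwelt above `block_voltage_min = 25` mV for at least
  `block_dwell_min = 1000` ms, otherwise *resting*.
- **Spiking traces**: all-singleton groups are *tonic spiking*, or
  *mixed-mode oscillation* when prominent subthreshold peaks (≥ 1 mV
  prominence, ≥ 0.5 per gap on average) fill the interspike gaps.
  All-multi-spike groups are *period-2 bursting* when odd/even inter-burst
  intervals separate cleanly (means differing by ≥ 10% of the overall
  mean, each parity tight), *two-cycle bursting with subthreshold
  oscillations* if subthreshold cycles also fill the gaps, *fast bursting*
  when the mean inter-burst interval is under `fast_ibi_max = 100` ms, and
  *periodic bursting* otherwise. Mixed singleton/multi sequences are
  *burst–spike alternating* when ≥ 75% of adjacent groups change type,
  else they fall back to the majority pattern.
- **Sensitive** = any spiking label (equivalently F > 0, excluding block,
  subthreshold/biphasic oscillation, resting and divergent points),
  matching the study's usage.

Each label is exercised by a deterministic synthetic fixture
(`prfield.fixtures`) built from spike/burst templates and sinusoidal
plateaus with the amplitudes and timings of the real regimes; these
fixtures validate the classifier without integrating the model, but they
are idealized — noiseless, perfectly periodic — so passing them shows the
decision logic is correct, not that the thresholds are optimal for noisy
experimental data.

## Sweeps and sensitivity intervals

Sweeps evaluate each grid point as an independent simulation from the same
printed initial state (no continuation), so results are pure per-point
functions, order-independent, and trivially parallelizable; the cost of
ignoring hysteresis is accepted because the protocol under reproduction
does the same. Sensitivity scans force the weak-DC baseline `Is = 0`,
`Id = 1` µA/cm² and use 1 mV field grids; `sensitivity_interval` returns
the maximal contiguous run of sensitive grid points (ties broken toward
more points, then the smaller lower endpoint).

## Known discrepancies

Against the study this package reproduces, with all conventions above:

- Sensitivity endpoints agree exactly or to 1 mV in 7 of 9 headline
  quantities. The two exceptions sit where the source contradicts itself:
  at `gc = 10` this package finds an upper endpoint of +11 mV (the source
  prints 9 in its results section but [−16, 11] in its conclusion), and at
  `VK = −100` a lower endpoint of −76 mV (the source prints −71 in one
  section and −77 in another).
- The zero-field regime catalogue matches in kind and location except for
  fine structure at bifurcation edges: burst–spike alternation appears
  near `gc ≈ 1.7` rather than exactly 1.8; no period-2 inter-burst
  alternation exists at `VK = −21` (clean 2-spike bursting instead); and
  for `VK > −5` the zero-field state is a stable depolarized equilibrium
  (classified as block) rather than a subthreshold oscillation —
  subthreshold oscillations do appear exactly where the source puts them
  once a negative field is applied (e.g. `VK = −5`, `Ve = −5`).

## Limitations

Single neuron only; no synaptic input, networks, AC or time-varying
fields, stochastic channels, or temperature effects. The regime
classifier's thresholds are conventions tuned to this model's voltage
scale and would need revisiting for other conventions (e.g. true
millivolt resting potentials near −65 mV). Firing-rate values near regime
boundaries are sensitive to the detection threshold; regime labels and
interval endpoints are the robust outputs.
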