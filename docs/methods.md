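# Methods

## Model

The chemical neuron (CN) is a closed set of at-most-bimolecular mass-action
reactions.  Input spikes are *boli*: at a spike time the system gains `β`
precursor molecules `I_i` which release the input species `A_i` at rate `κ`,
so inputs enter over a short but finite time and the system can reach a
stationary state under stationary input statistics.  `A_i` converts into the
shared internal-state species `B` both spontaneously (`k_AB`) and catalyzed
by the channel weight `H_i` (`k_cat` per catalyst molecule).  A receptor
species with `m` binding sites for `B` (modeled as a ladder of occupancy
states `C_0 … C_m`) provides the activation function: the fully occupied
state `C_m` is simultaneously the neuron's output and its learning signal.
While `C_m` is present, `A_i` converts into `H_i` (`k_learn`) — a Hebbian
update, since it requires input and output to coincide.  Weights and state
decay (`d_H`, `d_B`), which bounds the weights and lets the neuron forget.

Assumptions inherited by the implementation:

* conversion from the occupied receptor to its active form is instantaneous
  (`C_m` *is* the active form);
* cooperativity is a single slow final unbinding step: `C_m → C_{m−1} + B`
  runs at `ρ·k₋` with `ρ ≤ 1`, all other unbindings at `k₋`.  At equilibrium
  with clamped `B`, the occupancy of `C_m` is `φ^m/ρ` normalized over
  `{φ^j}` with `φ = k₊B/k₋`, a sigmoid in `B` whose fitted Hill exponent is
  bounded by `m` (the package exposes this closed form as an oracle);
* microreversibility: every conversion carries a reverse reaction, shipped
  at 10⁻³ × the forward rate; decays are irreversible (thermodynamic
  bookkeeping is out of scope);
* the threshold is reported as `ϑ = k₋/k₊`, the dissociation-ratio form at
  which a single site is half occupied.

The compartmentalized variant (c-CN) reinterprets channel indices as
compartments: `A` and the transporter `H` are single species located in
compartment `i`; the bulk copy of `A` is `B`.  The learning signal activates
`A → A*`; `A*` binds the promoter of a gene `h` whose product is the
transporter `H`; a small leak expression keeps the system bootstrappable.
Each compartment carries its own receptor chain driven by bulk `B` (so at
least `N` receptor copies exist).  Gene kinetics default to elementary
mass-action; the engine's Hill shortcut can replace the explicit chains.

## Calibrated default parameters ("default-cn")

Time is dimensionless; abundances are molecule counts.  The shipped defaults
(`src/chemneuron/data/default_cn.yaml`) are, per the package's own
calibration:

| parameter | value | rationale |
|---|---|---|
| β | 50 | bolus = half the threshold ϑ; single boli stay subthreshold, coincidences approach it |
| κ | 100 | bolus releases within ~0.01 time units (much faster than inter-spike gaps at 2–4 Hz) |
| k_AB | 5 | uncatalyzed conversion strong enough to bootstrap learning from `H = 0` |
| k_cat | 1 | at `H ≈ 100` catalyzed conversion (≈100/tu) outruns the state leak |
| k_learn | 2 | weight gain of order tens of molecules per coincidence |
| k₊, k₋ | 10, 1000 | ϑ = 100; chain equilibrates much faster than `B` changes |
| ρ | 0.01 | strong cooperativity; active-state lifetime 1/(ρk₋) = 0.1 |
| d_B | 20 | `B` lifetime 0.05 sets the coincidence window ≈ 0.1 time units |
| d_H | 0.01 | weight relaxation ≈ 100 time units; steady state within the 700-unit transient |
| E_total | 40 | receptor copy number at t = 0 |
| reverse rates | 10⁻³ × forward | microreversibility without disturbing the forward dynamics |

These values satisfy the separation of timescales (input/state/receptor fast
versus weights slow), make a single bolus trigger the learning signal when
the channel weight is ≈100 but not when it is 0, and place the
coincidence-detection window near 0.1 time units.  The calibration is a
package design choice: it reproduces the qualitative phenomenology
(frequency-bias and temporal-correlation learning, the nonlinearity optimum,
bolus-size degradation), not any particular printed trajectory.

## Input generation

Uncorrelated channels are Poisson: waiting times are exponential with mean
`1/f_i` (`f_i` in Hz; "parameter 1/f" is read as the mean, consistent with
`f` being a frequency).  Correlated channels form a chain; each leader event
spawns one follower event at lag `δ + ξ`, `ξ ~ N(0, σ²)`, clipped at zero
(negligible probability at the default `δ = 0.0047`, `σ² = 10⁻⁴`) and
dropped beyond the horizon.  Followers therefore inherit the leader's
renewal statistics exactly.  Schedules are deterministic functions of the
task seed.

## Simulation engine

*SSA*: Gillespie direct method over compiled reaction arrays (numba-compiled
kernel, pure-Python twin with the same contract).  Scheduled injections are
atomic state jumps; the pending reaction time is discarded and redrawn at
each injection, which is exact because exponential waiting times are
memoryless.  Recording is sample-and-hold on a fixed grid; a grid point
coinciding with an injection reports the post-injection state.  Runs are
bit-reproducible given the seed.

*ODE*: mass-action rate equations integrated piecewise between injection
times with LSODA (`rtol` 10⁻⁶ default); a same-species pair contributes
`k·x²/2`, matching the SSA combinatorics to O(1/x).

*Hill shortcut*: networks built without the explicit chain mark their
learning/activation reactions with a virtual catalyst whose abundance is
`E_total · B^m/(ϑ^m + B^m)` (computed in overflow-safe ratio form).  This
replaces the chain's equilibrium response and is available in both SSA and
ODE modes; it ignores B sequestration by the chain, so it is not used where
the resource-starvation effect matters.

## Statistics

Steady-state weights are time averages over `[transient, transient+window]`
(defaults 700 and 300 time units).  The *index of dispersion* is the
population standard deviation of the weights divided by their mean — a
scale-invariant discrimination measure; all-zero windows are flagged
degenerate rather than divided through.  The coincidence protocol measures
`ΔH₂/(ΔH₁+ΔH₂)` after one bolus per channel separated by `δ`, continuing
0.2 time units past the second bolus; replicates with zero total increase
are excluded and counted.

Sweep summaries additionally report a **noise-corrected dispersion**: the
between-channel variance of replicate-mean weights minus the estimated
sampling variance of those means (clipped at zero), square-rooted and
divided by the mean.  Raw per-replicate dispersion has a positive noise
floor that grows as weights shrink, which masks the collapse of
discrimination at high nonlinearity; the corrected statistic estimates the
systematic component and approaches zero for statistically identical
channels.  Where a single noise-robust location of the dispersion-vs-m curve
is needed (the optimum-shift check), the dispersion-weighted mean of `m` is
used instead of a raw argmax.

## DNA compilation (d-CN)

Signal species are two-domain strands (`A_n = <ta^ an>`, `H_n = <th^ hn>`,
`B = <tb^ b>`); the learning signal is the three-domain `<b te_m^ b>`.
Three catalytic reactions per channel — signal integration
`Fsi_n + A_n → A_n + B`, signal modulation `A_n + H_n → H_n + B`, and weight
accumulation `A_n + E → E + H_n` — each compile to a Join–Fork gate pair
expanded into six elementary steps: reactant-1 binding (waste released,
reversible), reactant-2 binding (translator released, reversible), Join
sealing, Fork triggering (first product out), helper-mediated second-product
release, Fork sealing.  Seal and helper strands with identical domain
content are shared between cascades.  The activation function is a single
polymer complex, `{tb^*} [b te0^]: [b te1^]<b>` for `m = 1`, extended by
`[b tb^]: [b tek^]` segments for larger `m`; it binds `m` copies of `B`
(alternating with stepping fuels, all steps reversible) before releasing the
learning signal.  Distinct channels share toeholds and are recognized by
their long domains, so the domain budget is `6 + N` core toeholds, `m + 1`
activation toeholds and `2 + 3N` long domains.

Design choices where the mapping was open:

* the signal-modulation reaction is implemented as the weight-catalyzed
  input conversion `A_n + H_n → H_n + B`, mirroring the CN's catalyzed
  reaction and drawing on the dedicated signal-modulation fuel pool;
* weight accumulation is compiled in its forward direction only (sealed
  gates cannot run backward); weight decay is carried entirely by the
  garbage collectors;
* the internal layout of Join/Fork duplex segments (which waste strand is
  displaced first) is schematic: it is consistent within the package's
  dialect and stoichiometrically audited, but not a claim about the
  nucleotide-level gate design;
* of the two periodic collector doses (12 and 0.1 μM every 1000 s), the
  larger goes to the `B` collector and the smaller to each `H_n` collector
  (the internal state turns over much faster than the weights);
* kinetic defaults are within measured strand-displacement ranges with the
  `ta`/`th` toeholds binding much more slowly, so input and weight strands
  react on the signal timescale; all rates are config-exposed.

Units in the DNA circuit are μM and seconds; fuels default to 25 000 μM
(signal modulation), 50 000 μM (signal integration) and 10 000 μM (weight
accumulation), boli to 10 μM.  With these defaults the fluid-limit
simulation of the compiled three-channel circuit distinguishes a 2× spike
frequency bias within ~1.5·10⁵ s; the free `B` level saturates the
activation polymer in long runs (the printed collector doses remove only a
small fraction), which is acceptable for the frequency-bias behavior but
means quantitative temporal-order resolution in DNA would need a larger
collector budget.

## What the synthetic tasks do and do not show

The generators produce idealized stationary Poisson/chained-renewal boli
with exact sizes.  Real molecular inputs would arrive with variable bolus
sizes, non-stationary rates and delivery noise; passing the FB/TC suites
shows the mechanism discriminates clean statistical structure, not that it
is robust to input-amplitude noise.  The CN's time units are dimensionless;
no physical rate mapping is attempted except in the DNA circuit.

## Problem sizes

The shipped protocols use 1000-time-unit runs (700 transient + 300
averaging), 8–20 seeds per ordering claim, 1000 replicates of the 0.2-unit
coincidence protocol, and 4 replicates per grid point of the 10×2
nonlinearity sweep — sizes chosen so the full suite completes on a single
CPU in well under half an hour while leaving each assertion statistically
comfortable.

## Known limitations

* No tau-leaping or hybrid simulation; very stiff SSA regimes (large
  `E_total` with fast chain kinetics) are slow.
* The Hill shortcut ignores `B` sequestration, so it cannot reproduce the
  resource-starvation optimum.
* The d-CN compiler covers the fixed gate motifs of this circuit, not
  general DSD enumeration; leak reactions and buffered/timer variants are
  out of scope.
* Acceptance of the FB/TC orderings is statistical (replicate means and
  seed fractions), not a per-run guarantee.
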