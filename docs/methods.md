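# Methods

`canet` simulates a chain of cortical-like areas in which repeated,
single-item sensory stimulation makes *cell assemblies* (CAs) emerge:
distributed sets of strongly and reciprocally connected cells that behave
as discrete, bistable functional units.  This note documents the model, the
parameter choices that matter, what the synthetic stimuli do and do not
emulate, and the design decisions taken where the design was genuinely
open.

## Architecture

The network is a chain of `areas` (default 6) identical areas.  Each area
holds a `rows x cols` grid (default 25 x 25 = 625) of excitatory
graded-response cells and a matched grid of inhibitory cells.  Excitatory
wiring is sparse, random and topographic: a cell may contact only cells
within a square Chebyshev neighbourhood of halfwidth `kernel_halfwidth`
centred on its corresponding grid position in the target area (clipped at
the borders; a toroidal option exists for homogeneity experiments), and
each potential synapse exists independently with probability `density`.

Three projection classes are drawn once and then structurally frozen —
plasticity moves weights, never the mask:

| projection | halfwidth | density | mean fan-out |
|---|---|---|---|
| within-area recurrent   | 3 | 0.35 | ~15 |
| forward (area n -> n+1) | 5 | 0.28 | ~30 |
| backward (area n+1 -> n)| 5 | 0.28 | ~30 |

These numbers were chosen so that (a) total fan-in per cell is O(10^2),
small against 625 — preserving the sparse, "not all-to-all" character the
model class depends on; (b) membership in an assembly is *connectivity
quantized*: with ~20 member cells per area, a typical cell receives well
under one active synapse by chance, so membership requires the rare
coincidence of several converging contacts, which is what keeps different
items' assemblies nearly disjoint; and (c) the between-area fan is large
enough that an area with ~20 consolidated cells offers a sufficient pool of
multi-synapse candidates in the next area — the condition for assembly
formation to propagate through the whole six-area depth rather than stall
after the first synapse from each stimulated end.  Initial weights are
uniform on [0, 0.3] (w_max = 0.65), which keeps the blank network
subcritical: noise alone cannot percolate activity.

## Dynamics

All cells are leaky integrators with unit-step synchronous updates
(time constants in steps).  Excitatory net input is

    external + synaptic drive - local inhibition - global inhibition
    - adaptation + noise,

low-pass filtered with `tau_membrane` = 2.5; output is a piecewise-linear
squash (0 below `phi` = 0.25, unit slope over one unit, saturated at 1).
Uniform noise (amplitude 0.25) is always on: it breaks symmetry during
learning and makes the attractor claims non-trivial.

Inhibition is two-tier:

* **Local**: each inhibitory cell integrates 0.25 x the summed excitatory
  output of its 5 x 5 neighbourhood (`tau_inhib` = 3) and subtracts
  `local_inhib_gain` = 2.0 times its output from its matched excitatory
  cell.  The input scaling makes a lone active cell nearly self-inhibition
  free while a crowded patch is strongly suppressed — a soft
  winner-take-all per patch that disperses assemblies spatially and caps
  their local density.
* **Global**: one slow variable per area tracks the area's summed output
  (`tau_global` = 2.5).  Its subtractive effect is linear (gain 0.045) up
  to a saturation at 16 summed-output units, plus a weak quadratic term
  (2e-4) that only engages far above the assembly scale.  The saturation is
  deliberate: the linear slope below ~one-assembly activity provides the
  capacity competition that keeps learning selective, while the flat region
  above it leaves the headroom needed for two (or more) assemblies to be
  co-active — the whole point of the superposition experiments.  The
  quadratic term is a far-field safety against runaway recruitment.

Spike-rate adaptation (`adapt_strength` = 0.5, `tau_adapt` = 120) tracks
each cell's own output.  It serves three roles: it is the slow negative
feedback that turns "everything active" into an unstable regime during
learning (see below), it produces the fade of insufficiently consolidated
assemblies after stimulus removal, and its strength is the main knob
separating the self-sustained from the fading working-memory regime.

## Plasticity

All excitatory projections learn with a local rule in the
Artola–Bröcher–Singer mold: the sign of the change depends on the
*postsynaptic membrane potential* against two thresholds and on the
*presynaptic output* against two thresholds.

* LTP (`+delta_w`, 0.004): presynaptic output >= `theta_pre` (0.5) and
  postsynaptic potential >= `theta_plus` (0.35).  Weights saturate at
  `w_max`.
* Homosynaptic LTD (`-0.55 delta_w`): presynaptic cell active but
  postsynaptic potential in the intermediate window [0.10, 0.35).
* Heterosynaptic LTD (`-4 x 0.55 delta_w`): presynaptic output below
  `theta_silent` (0.10) while the postsynaptic cell is strongly
  depolarized.  Presynaptic cells between `theta_silent` and `theta_pre`
  trigger no change.

Three asymmetries here are load-bearing and were adopted after the
symmetric variant failed reproducibly:

1. *LTD weaker than LTP* (x0.55).  At every trial onset the membrane ramps
   through the LTD window before reaching the LTP zone; with symmetric
   steps this ramp tax makes every nascent response erode and learning
   never leaves the stimulated areas.
2. *Heterosynaptic LTD stronger than homosynaptic* (x4).  A cell contested
   by two emerging assemblies has its cross-links potentiated on one item's
   trials and heterosynaptically depressed on the other's; only when
   depression wins this tug-of-war do contested cells retreat into the
   assemblies' halos instead of fusing the two circuits.
3. *A silent zone below theta_pre*.  Heterosynaptic depression must target
   links from genuinely silent cells; members that are merely late in the
   ignition ramp (intermediate output) must not be treated as absent, or
   the rule thins the assembly's own kernel.

There is no weight normalisation or homeostatic scaling anywhere.

## Training

Each trial presents one item's binary pattern pair (19 of 625 cells in the
first and last area, amplitude 4.5) for 14 steps with learning on, then
resets the fast dynamic state and runs a 4-step silent interval.  The reset
at stimulus offset enforces strict temporal anti-correlation between items
— the premise of the LTD pruning argument — and plays the role of the
between-trial activity wipe needed whenever learned attractors would
otherwise persist into the next trial.  The slow adaptation variable is
*not* reset: a cell active in every trial regardless of item accumulates
adaptation across trials and loses its edge.  This cross-trial
intrinsic-excitability memory is what prevents the pathological solution in
which one stimulus-independent "club" of well-connected cells captures
every item (a failure mode that otherwise appears robustly), while an
item-selective cell, active in 1/n_items of trials, is essentially
unaffected.

Items are presented in randomized balanced order, `presentations_per_item`
= 3000 by default.  The desk-scale configuration used by the test suite and
the acceptance script keeps the full architecture and all 12 items but
trains 600 presentations per item (~35k trials, a few minutes on one CPU);
assemblies are fully formed and the overlap statistics are stable well
before that point.

Stimulus patterns are drawn uniformly without replacement, with the
constraint that two stimuli delivered to the same area share at most one
active cell (`min_hamming_active` = 18).  Unconstrained draws occasionally
produce pairs sharing 3–4 cells; such shared cells are driven to full
output by both items, their efferents saturate toward both assemblies, and
— because no branch of the learning rule ever depresses a synapse whose
presynaptic cell is active while the postsynaptic cell is fully silent —
they become permanent hubs through which one assembly ignites the other,
fusing the pair.  Capping the overlap at one cell keeps the stimuli
essentially random while matching the premise that the learned items are
distinct.  A stress configuration can raise the overlap deliberately to
probe halo growth.

## Assembly extraction and overlap

With learning off, each item is probed for 30 steps from a reset state and
every cell's output is averaged over the last 15 (excluding the ignition
transient).  M is the maximal averaged response over *all* areas; a cell
belongs to the item's assembly at threshold gamma iff its response reaches
gamma * M (so membership is invariant to rescaling the profile), and to the
kernel iff it reaches 0.75 * M.  Overlap between two assemblies is
100 * |intersection| / min(|A|, |B|) — the most conservative denominator,
producing the largest percentages; union and mean-cardinality bases are
available.  The gamma grid is 0.50–0.90 in steps of 0.05.  All six areas
are counted, including the stimulated peripheral ones (a switch restricts
the count to central areas).

## Experiments

An assembly is "on" in a window when at least `theta_frac` = 0.5 of its
kernel cells average output >= `theta_on` = 0.5.  The criterion is
evaluated over the central areas by default: input-free reverberation in
the two stimulated peripheral areas is characteristically weak and partial
(only a few cells of the original input pattern are reconstructed), so
including them would measure pattern reconstruction rather than
working-memory state.

* **Ignition**: 25 steps of stimulation, judged over the last third.
* **Persistence**: ignite, remove input, observe >= 500 steps.  The
  reference level is taken after ~2.5 adaptation time constants, because a
  freshly ignited assembly settles from its stimulation-driven peak to its
  reverberant level as adaptation equilibrates; "self-sustained" means the
  settled kernel activity never falls below `theta_on` of that level, and
  the drift statistic reports the worst relative excursion of a 100-step
  running mean.
* **Superposition (t0–t8)**: ignite item A and let it settle (t0, 120
  steps); stimulate item B's pattern pair for 4 x 20 steps (t1–t4); remove
  all input for 4 x 40 steps (t5–t8).  At t4 the decoded on-set over all
  learned items must equal {A, B}; after removal the sustained assembly
  must survive with small relative change of its kernel activity
  (interference), and in the default regime the probed assembly — chosen
  among items whose circuits are not strong enough to self-sustain — fades,
  returning the network to within a relative L2 distance epsilon = 0.05 of
  its pre-probe state.  The protocol refuses item pairs that were ever
  co-presented during training (checked against the training record).

Whether a given item's circuit self-sustains depends on the connectivity
lottery: items whose middle-area kernels recruited >= ~8 cells per area
with >= 4–5 saturated within-kernel contacts persist indefinitely (drift
well under 10%), thinner ones fade within a few hundred steps.  At the
desk-scale presentation count roughly two thirds of items persist; both
regimes are exercised by the experiments.

## What the synthetic stimuli do and do not emulate

The stimulus set models arbitrary, unrelated sensory items: sparse, binary,
spatially unstructured, noiseless, and presented in isolation with fixed
duration.  It does not model correlated or graded features, category
structure, temporal sequences within an item, or co-occurrence statistics
— so passing tests show that *independently experienced* items develop
quasi-orthogonal, co-activatable representations, and say nothing about
generalisation across similar stimuli, which this representational style
trades away by design.

## Numerical choices and degenerate inputs

Synchronous updates, float64 state, float32 recorded traces.  All
randomness derives from `master_seed` through named, order-independent
substreams (connectivity, patterns, schedule, training noise, probe noise,
experiment noise); two runs from the same config are bit-identical.
Non-finite potentials abort with the offending area and step.  A density-0
projection, an empty schedule, gamma outside (0, 1], co-trained
superposition pairs, and probing an untrained (all-zero response) network
raise immediately.  Empty assemblies at high gamma cause the affected pair
to be skipped and logged rather than poisoning the report.

## Known limitations

* No conduction delays, no spiking, no oscillatory readout; the
  fixed-point attractor regime is the only persistence mode studied.
* Inhibitory wiring is fixed and non-plastic.
* The persistence/fade boundary is a lottery over the connectivity draw;
  per-item outcomes vary across seeds even though the population-level
  statistics are stable.
* Very unlucky connectivity draws can still leave one item pair with
  elevated overlap at desk-scale training; the overlap statistics quoted
  in the README refer to the default configuration and seeds actually run.
* Capacity questions (how many assemblies fit, how co-activation scales
  with depth) are reachable through the config but not studied here.
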