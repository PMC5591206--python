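# Methods

## Model summary

`plastnet` simulates supervised learning of Boolean input–output rules
in spatially embedded random networks of discrete-time
integrate-and-fire neurons.  The teaching signal is purely negative
feedback: weights change only after a wrong answer, by an amount that
decays with the Euclidean distance between the output neuron (where
the adaptation signal is assumed to be released) and the postsynaptic
neuron of each activated synapse.  The package provides the network
generator, the dynamics, the plasticity rule, the training loop, and
ensemble sweep machinery with binomial confidence intervals.

## Parameters

| parameter | meaning | default | units |
|---|---|---|---|
| `N` (`n_hidden`) | hidden neurons | — | count |
| `density` | neurons per unit area; sets `L = sqrt(N/density)` | 1.0 | 1/length² |
| `d0` | scale of the exponential connection-distance draw | 2.0 | length |
| `out_degree` | outgoing connections per input/hidden neuron | 10 | count |
| `p_inh` | inhibitory fraction among hidden neurons | 0.0 | — |
| `v_max` | firing threshold | 1.0 | potential |
| `Δη` (`delta_eta`) | transmitter decrement per firing | 0.2 | — |
| `t_refr` | refractory duration | 1 | steps |
| `α` (`alpha`) | adaptation strength; also the weak-activity boost | 0.001 | — |
| `r0` | learning length (spatial decay of adaptation) | — | length |
| `ω_max` (`omega_max`) | weight cap | 2.0 | potential |
| `critical_factor` | growth per silent pass during initialization | 0.001 | — |
| `T_max` (`t_max`) | learning-step budget | 10,000 | steps |

The neuron density is not a quantity the model pins down; we fix
`density = 1` (so `L = sqrt(N)`) and expose it as a knob.  With
`N = 1000` this puts `L ≈ 31.6`, so the well-performing learning
length `r0 = 10` sits at `r0/L ≈ 0.32`, inside the high-performance
plateau of the success-rate curve — consistent with the benchmark
phenomenology the package reproduces.

## Design choices in the topology

* **Nearest-to-draw wiring.**  "A neuron at a distance sufficiently
  close to the drawn `d`" is resolved deterministically: the candidate
  whose distance is closest to the draw, ties to the lowest index,
  candidates already connected to the same source excluded.  This is
  parameter-free, always succeeds and is exactly reproducible.  The
  price is a distortion at short distances: draws below the typical
  nearest-neighbour spacing (≈ 0.5 at density 1) are rounded up to the
  nearest available neuron, so the realized distance distribution is
  an exponential with a depleted head (measured at `N = 4000`,
  `d0 = 2`: mean ≈ 2.2 instead of 2.0, Kolmogorov–Smirnov distance
  ≈ 0.16 against the ideal exponential).  The test suite freezes these
  oracle-measured bounds.
* **Degree bookkeeping.**  Every input and hidden neuron has exactly
  `out_degree` outgoing synapses; the output's `out_degree` incoming
  synapses come from its nearest hidden nodes and count toward those
  nodes' out-degree, so the synapse total is `(N + 4)·out_degree`.
* **Roles are protected.**  Input and output neurons are always
  excitatory, inputs receive no synapses, the output sends none, and
  hidden distance draws target hidden neurons only.  An input neuron
  that could be re-excited mid-trial would corrupt the input code.
* **Geometry.**  Inputs at `(0, kL/5)`, `k = 1..4`; output at
  `(L, L/2)`; hard walls (no periodic distances).

## Design choices in the dynamics

* **Update order within a step.**  (1) the firing set is every neuron
  with `v ≥ v_max` and no refractory countdown; (2) transmitted
  amounts are computed from a snapshot of `v` and `η` at the step
  start; (3) firing neurons' potentials reset to 0; (4) deliveries
  land on every non-refractory target — including, when `t_refr = 0`,
  a target that fired this very step (the delivery lands on the
  cleared potential and persists).  Discarding such same-step
  deliveries instead would add a hidden dissipation channel the model
  does not intend.
* **Same-step refractory dialect.**  When `t_refr > 0`, a neuron
  entering the refractory state already blocks deliveries arriving at
  its own firing step.  The alternative reading (accept deliveries at
  the firing step, block only afterwards) is exposed as
  `refr_same_step=False`; the excitatory XOR fixture works under both.
* **Transmitter floor.**  `η` is clamped at 0; a depleted neuron still
  fires (resetting its potential, becoming refractory, and counting
  toward `n_act`) but transmits nothing.  Note that with binary
  `Δη = 0.2` the fifth decrement leaves `η ≈ 7·10⁻¹⁷`, not exactly 0.
* **Overshoot.**  Potentials may exceed `v_max` before firing; the
  linear activation transmits the actual `v_i`, and the full potential
  is discarded on reset.
* **Termination.**  Finite transmitter bounds the number of
  transmitter-bearing firings by `⌈1/Δη⌉` per neuron, and every firing
  needs a fresh delivery, so activity always halts.  A generous step
  cap (`10·n·(⌈1/Δη⌉+1)`) guards against implementation bugs only.
* **Engines.**  The numpy step loop in `dynamics.py` is the reference
  semantics; a numba kernel replays the same arithmetic in the same
  accumulation order and is verified bit-identical by the test suite.
  Trials, training and sweeps are exactly reproducible from the
  topology seed; the dynamics itself is deterministic.

## Design choices in learning

* **Sign convention.**  "Strengthen" always pushes the network toward
  firing: excitatory magnitudes grow and inhibitory magnitudes shrink
  by `α·ω·n_act·K(r)`; "weaken" is the mirror image.  Weights are
  magnitudes clamped to `[0, ω_max]`; the presynaptic neuron carries
  the sign.
* **Kernel.**  Exponential `exp(−r/r0)` by default; the Gaussian
  variant uses the standard form `exp(−r²/(2r0²))` with scale `r0`.
* **Synapse position.**  `r` is measured to the postsynaptic neuron,
  reflecting the assumption that a synapse sits much closer to the
  postsynaptic than to the presynaptic cell.  Input-neuron synapses
  adapt like any others.
* **Critical initialization.**  All rule inputs are presented in
  order; the check runs after each single input and stops immediately
  at the first output spike; the multiplicative boost is applied once
  per completed silent pass.  The boost count is capped (default 10⁵)
  to turn an unreachable output into an explicit error.
* **Success detection.**  Training tracks consecutive correct answers
  and succeeds when they span one full cycle, which matches
  "sequentially all relations learned" without a separate frozen
  evaluation pass.  The weak-activity boost counts as a learning step;
  otherwise a network whose output potential never moves could loop
  below `T_max` forever.
* **Adaptation timing.**  Adaptation is applied immediately after each
  wrong presentation, using only that presentation's activation
  record.

## What the generator emulates — and what it does not

The synthetic networks are the study's objects themselves (the model
is self-contained; there is no external data).  The ensembles emulate
the benchmark conditions: constant density, 10-regular out-degree,
exponential connection lengths, and the fixed 15-pattern rule table.
They do not emulate biological realism beyond that: no synaptic
delays, no noise, no leak currents, no transmitter recovery within a
trial, no 3-D geometry.  Passing tests therefore demonstrate the
model's internal phenomenology, not predictions about tissue.

## Ensemble measurement

Success rates use replicate seeds `base_seed + i`, so results are
independent of execution order or worker count.  Binomial uncertainty
is a 95% Wilson score interval, chosen because the interesting regimes
sit at `s ≈ 0` and `s ≈ 1` where Wald intervals degenerate.  Per-
replicate failures (exceptions) are recorded in the result row rather
than aborting a sweep; sweeps checkpoint one CSV row per cell and
resume from it.

At full scale the benchmark curves use ensembles of 2000 networks;
the package's test suite and the acceptance script run desk-scale
ensembles of 10–20 networks with confidence-interval-aware margins,
and the smaller property tests use networks of 30–300 hidden neurons.

## Known limitations

* The desk-scale ensembles (10–20 replicates) resolve success rates
  only to about ±0.2; curve-shape assertions are deliberately coarse
  one-sided comparisons.
* The nearest-to-draw wiring distorts the connection-length
  distribution below the inter-neuron spacing (see above); at
  `d0 ≲ 0.5` and density 1 the realized distribution is dominated by
  that floor.
* With the linear (voltage-proportional) activation and `t_refr = 0`,
  transmitter depletion is the only remaining non-monotonicity in the
  dynamics: neurons that fire repeatedly waste releasable transmitter,
  so a stronger input can deliver *less* signal downstream.  In this
  implementation the adaptation rule readily discovers and exploits
  that channel, so such networks still learn the benchmark rules even
  though they lack both refractory and threshold-clipping inhibition;
  see the test suite for the regimes in which refractoriness is and is
  not required.
* Sweeps parallelize per cell (joblib) but the simulation itself is
  single-threaded.
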