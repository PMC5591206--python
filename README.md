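# plastnet

Spatially embedded spiking neural networks that learn Boolean rules
through a plastic-adaptation signal decaying with Euclidean distance.

## The scientific problem

Biologically plausible learning rules cannot propagate error gradients
antidromically through synapses.  One alternative is a feedback signal
released into the extracellular space — monoamines such as dopamine are
known to mediate plasticity over spatial ranges of tens to thousands of
synapses.  `plastnet` implements a model for studying this idea: random
networks of integrate-and-fire neurons embedded in a 2-D square learn
input–output relations when *wrong* answers trigger synaptic changes
whose strength decays with the Euclidean distance from the output
neuron, where the teaching signal is assumed to be released.  The
central question is how the spatial extent of that signal (the
*learning length* `r0`) and the spatial structure of the network (the
*characteristic synaptic length* `d0`) shape the learning performance.

## The model

**Topology.**  `N` hidden neurons are placed uniformly in a square of
side `L = sqrt(N / density)` (area ∝ `N`, constant density).  Four
input neurons sit on the left edge, one output neuron on the right.
Every input and hidden neuron makes 10 directed connections; hidden
neurons wire by drawing a target distance `d` from
`p(d) = exp(−d/d0) / d0` and connecting to the unconnected neuron whose
distance best matches the draw.  Inputs connect to their nearest
neighbours; the output receives from its 10 nearest nodes.  A fraction
`p_inh` of hidden neurons may be inhibitory.

**Dynamics.**  Discrete synchronous time steps.  A neuron fires when
`v_i ≥ v_max = 1`; each firing delivers

    v_j(t+1) = v_j(t) ± ω_ij · η_i          (heaviside activation)
    v_j(t+1) = v_j(t) ± ω_ij · η_i · v_i    (linear activation)

to its targets (− for inhibitory senders), resets `v_i` to 0, depletes
the releasable transmitter `η_i` by `Δη = 0.2` and makes the neuron
refractory for `t_refr` steps, during which it can neither send nor
receive.  Finite transmitter guarantees every trial terminates.  A
binary input pattern makes the corresponding input neurons fire once;
the answer is 1 iff the output neuron fires at all.

**Learning.**  Weights start weak (1.0 from inputs, 0.1 elsewhere) and
are multiplied by 1.001 per silent pass until the first input fires the
output — the *critical point*.  Then patterns are presented cyclically;
every wrong answer adapts each synapse activated during the trial:

    Δω_ij = ± α · ω_ij · n_act · exp(−r / r0)

with `α = 0.001`, `n_act` the synapse's activation count, `r` the
distance from the output neuron to the postsynaptic neuron, and a
Gaussian kernel `exp(−r²/2r0²)` as an alternative.  Strengthening
(target 1, no output spike) pushes the network toward firing, weakening
the reverse; weights are clamped to `[0, ω_max = 2]`.  If the output
potential never moved at all, every weight gets a small global boost
instead.  Training succeeds when a full cycle of presentations is
answered correctly, and fails after `T_max` learning steps.

**Measurement.**  The *success rate* `s` is the fraction of an ensemble
of independently generated networks (seeds `base_seed + i`) that learn
the rule within `T_max`, reported with a 95% Wilson interval.  The
benchmark rule set — 15 Boolean functions of 4 inputs, usually the
first 10 — ships as package data.

## Worked example

```python
import plastnet as pn

cfg = pn.TopologyConfig(n_hidden=100, d0=2.0, seed=1)
net = pn.generate_network(cfg)
print(f"L = {cfg.side_length:.2f}, neurons = {net.n_neurons}, synapses = {net.n_synapses}")

rule = pn.load_rule("first3")
dyn = pn.DynamicsConfig(t_refr=1)
learn = pn.LearningConfig(r0=3.0)
net, boosts = pn.critical_initialization(net, rule, dyn, learn)
print(f"critical point after {boosts} boosts")

res = pn.train(net, rule, dyn, learn, t_max=10_000)
print(f"learned = {res.learned} in {res.learning_steps} learning steps "
      f"({res.boosts} weak-activity boosts)")

row = pn.success_rate(pn.CellParams(n_hidden=100, r0=3.0, rule="first3", t_max=10_000),
                      ensemble_size=10, base_seed=1)
print(f"s = {row['s']:.2f}  (95% CI {row['ci_low']:.2f}-{row['ci_high']:.2f})")
```

prints

```
L = 10.00, neurons = 105, synapses = 1040
critical point after 969 boosts
learned = True in 733 learning steps (276 weak-activity boosts)
s = 1.00  (95% CI 0.72-1.00)
```

i.e. a 105-neuron network reaches the edge of responsiveness after 969
global weight boosts, learns the three-pattern rule in 733 adaptation
events, and all ten ensemble replicates at these parameters succeed
(the Wilson interval reflects the small ensemble).

The same workflow is available from the shell:

```sh
plastnet generate --n 1000 --d0 2 --seed 42 --out net.json
plastnet trial --net net.json --pattern 1010 --t-refr 1
plastnet train --net net.json --rule first10 --r0 10 --tmax 100000
plastnet sweep --config sweep.yaml --out results.csv
plastnet plot --in results.csv --out results.png
```

An eight-neuron, purely excitatory XOR gate
(`pn.xor_motif()`) demonstrates the key mechanism: with a one-step
refractory period, timing differences alone can suppress the output
when both inputs are active, so non-linearly separable functions are
computable without inhibitory synapses.

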