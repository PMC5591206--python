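"""Discrete-time synchronous integrate-and-fire dynamics.

All neurons update in lockstep.  A neuron fires when its potential
reaches the threshold ``v_max`` and it is not refractory; each firing
delivers ``±ω_ij·η_i`` to every postsynaptic neuron ``j`` (minus sign
for inhibitory presynaptic neurons), resets the potential to zero,
depletes the releasable transmitter ``η_i`` by ``Δη`` and makes the
neuron refractory for ``t_refr`` steps, during which it can neither
receive nor send.  Because η is finite and never recovers within a
trial, activity always dies out.

The alternative ``linear`` activation scales the transmitted signal by
the firing neuron's actual potential: ``±ω_ij·η_i·v_i``.

A trial presents one binary input pattern (bit 1 makes the
corresponding input neuron fire once at the first step) and runs until
quiescence, accumulating the per-synapse activation counts ``n_act``
that drive plastic adaptation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .topology import ConfigurationError, NetworkSpec

__all__ = [
    "DynamicsConfig",
    "DynamicsState",
    "TrialRecord",
    "SimulationDivergenceError",
    "reset_state",
    "apply_input",
    "step",
    "run_trial",
]

HEAVISIDE = "heaviside"
LINEAR = "linear"


class SimulationDivergenceError(RuntimeError):
    """A trial exceeded its step cap — activity failed to die out,
    which the transmitter-depletion bound rules out for a correct
    implementation."""


@dataclass(frozen=True)
class DynamicsConfig:
    """Parameters of the firing dynamics.

    Parameters
    ----------
    v_max:
        Firing threshold.
    delta_eta:
        Transmitter decrement per firing; ``⌈1/Δη⌉`` bounds the number
        of effective releases per neuron and guarantees termination.
    t_refr:
        Refractory duration in time steps (0 disables refractoriness).
    activation:
        ``"heaviside"`` transmits ``ω·η``; ``"linear"`` transmits
        ``ω·η·v`` with the firing neuron's actual potential.
    step_cap:
        Hard iteration limit; ``None`` selects ``10·n·(1/Δη + 1)``.
    refr_same_step:
        Dialect flag: when True (default), a neuron entering the
        refractory state already blocks deliveries arriving at its own
        firing step.
    """

    v_max: float = 1.0
    delta_eta: float = 0.2
    t_refr: int = 1
    activation: str = HEAVISIDE
    step_cap: int | None = None
    refr_same_step: bool = True

    def __post_init__(self) -> None:
        if not self.v_max > 0:
            raise ConfigurationError("v_max must be > 0")
        if not 0 < self.delta_eta <= 1:
            raise ConfigurationError("delta_eta must lie in (0, 1]")
        if self.t_refr < 0:
            raise ConfigurationError("t_refr must be >= 0")
        if self.activation not in (HEAVISIDE, LINEAR):
            raise ConfigurationError(f"unknown activation {self.activation!r}")

    def resolve_step_cap(self, n_neurons: int) -> int:
        if self.step_cap is not None:
            return self.step_cap
        return int(10 * n_neurons * (np.ceil(1.0 / self.delta_eta) + 1))


@dataclass
class DynamicsState:
    """Mutable per-neuron state at one time step."""

    v: np.ndarray  # membrane potential
    eta: np.ndarray  # releasable transmitter in [0, 1]
    refr: np.ndarray  # remaining refractory steps
    t: int = 0


@dataclass
class TrialRecord:
    """Outcome of one input presentation."""

    output_fired: bool
    output_voltage_changed: bool
    n_act: np.ndarray  # per-synapse activation counts
    firings: np.ndarray  # (k, 2) array of (time, neuron id)
    duration: int

    @property
    def output_bit(self) -> int:
        return int(self.output_fired)


def reset_state(net: NetworkSpec) -> DynamicsState:
    """Fresh state: ``v = 0``, ``η = 1``, no refractoriness."""
    n = net.n_neurons
    return DynamicsState(
        v=np.zeros(n), eta=np.ones(n), refr=np.zeros(n, dtype=np.int64), t=0
    )


def apply_input(
    state: DynamicsState, pattern, net: NetworkSpec, cfg: DynamicsConfig
) -> DynamicsState:
    """Encode a binary pattern: bit-1 input neurons are primed to fire
    at the first step (potential set to threshold)."""
    pattern = np.asarray(pattern, dtype=int)
    inputs = net.input_ids
    if pattern.shape != (len(inputs),):
        raise ValueError(
            f"pattern must have {len(inputs)} bits, got shape {pattern.shape}"
        )
    state.v[inputs[pattern == 1]] = cfg.v_max
    return state


def _gather_ranges(indptr: np.ndarray, ids: np.ndarray) -> np.ndarray:
    """Concatenate ``arange(indptr[i], indptr[i+1])`` for each id, in order."""
    starts = indptr[ids]
    counts = indptr[ids + 1] - starts
    total = int(counts.sum())
    if total == 0:
        return np.empty(0, dtype=np.int64)
    offsets = np.concatenate(([0], np.cumsum(counts)[:-1]))
    return np.arange(total) + np.repeat(starts - offsets, counts)


def step(state: DynamicsState, net: NetworkSpec, cfg: DynamicsConfig):
    """Advance one synchronous time step (in place).

    Returns ``(state, fired, activated)`` where ``fired`` holds the
    indices of neurons that fired this step and ``activated`` the
    indices of synapses whose delivery reached a non-refractory target.
    """
    v, eta, refr = state.v, state.eta, state.refr
    can_fire = (v >= cfg.v_max) & (refr == 0)
    fired = np.flatnonzero(can_fire)
    activated = np.empty(0, dtype=np.int64)

    if fired.size:
        syn_idx = _gather_ranges(net.indptr, fired)
        if syn_idx.size:
            counts = net.indptr[fired + 1] - net.indptr[fired]
            pre = np.repeat(fired, counts)
            posts = net.syn_post[syn_idx]
            blocked = refr[posts] > 0
            if cfg.t_refr > 0 and cfg.refr_same_step:
                blocked |= can_fire[posts]
            ok = ~blocked
            activated = syn_idx[ok]
            pre_ok = pre[ok]
            base = np.where(net.inhibitory[pre_ok], -1.0, 1.0) * eta[pre_ok]
            if cfg.activation == LINEAR:
                base = base * v[pre_ok]
            amounts = net.weights[activated] * base
            # reset before delivery: a neuron firing this step discards
            # its potential but still receives simultaneous deliveries
            # (unless refractoriness blocks them)
            v[fired] = 0.0
            v += np.bincount(posts[ok], weights=amounts, minlength=len(v))
        else:
            v[fired] = 0.0
        eta[fired] = np.maximum(eta[fired] - cfg.delta_eta, 0.0)

    refr[refr > 0] -= 1
    if fired.size:
        refr[fired] = cfg.t_refr
    state.t += 1
    return state, fired, activated


def run_trial(
    net: NetworkSpec,
    pattern,
    cfg: DynamicsConfig | None = None,
    engine: str = "auto",
) -> TrialRecord:
    """Simulate one input presentation until activity dies out.

    Parameters
    ----------
    net:
        The network to simulate (weights are read, never written).
    pattern:
        Binary input vector, one bit per input neuron.
    cfg:
        Dynamics parameters (defaults: threshold 1.0, ``Δη = 0.2``,
        ``t_refr = 1``, heaviside activation).
    engine:
        ``"numpy"`` runs the reference step loop, ``"numba"`` a
        compiled kernel with identical arithmetic, ``"auto"`` picks the
        compiled kernel when available.
    """
    if cfg is None:
        cfg = DynamicsConfig()
    step_cap = cfg.resolve_step_cap(net.n_neurons)

    if engine == "auto":
        from ._engine import HAVE_NUMBA

        engine = "numba" if HAVE_NUMBA else "numpy"

    if engine == "numba":
        from ._engine import run_trial_numba

        return run_trial_numba(net, pattern, cfg, step_cap)
    if engine != "numpy":
        raise ValueError(f"unknown engine {engine!r}")

    state = reset_state(net)
    apply_input(state, pattern, net, cfg)
    out_id = net.output_id
    n_act = np.zeros(net.n_synapses, dtype=np.int64)
    firings: list[np.ndarray] = []
    output_fired = False
    out_changed = False

    while True:
        if not np.any((state.v >= cfg.v_max) & (state.refr == 0)):
            break
        if state.t >= step_cap:
            raise SimulationDivergenceError(
                f"trial exceeded step cap {step_cap}; activity should "
                "terminate under transmitter depletion"
            )
        t_now = state.t
        state, fired, activated = step(state, net, cfg)
        if fired.size:
            firings.append(
                np.column_stack((np.full(fired.size, t_now, dtype=np.int64), fired))
            )
            if np.any(fired == out_id):
                output_fired = True
        if activated.size:
            n_act[activated] += 1
            if not out_changed and np.any(net.syn_post[activated] == out_id):
                out_changed = True

    firings_arr = (
        np.concatenate(firings) if firings else np.empty((0, 2), dtype=np.int64)
    )
    return TrialRecord(
        output_fired=output_fired,
        output_voltage_changed=out_changed,
        n_act=n_act,
        firings=firings_arr,
        duration=state.t,
    )
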