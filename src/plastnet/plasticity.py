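"""Distance-dependent synaptic adaptation.

When the network answers wrongly, every synapse that was activated
during the trial changes by

    Δω_ij = ± α · ω_ij · n_act · K(r)

where ``r`` is the Euclidean distance from the output neuron to the
postsynaptic neuron (the adaptation signal is released at the output
and decays in space), ``n_act`` counts how often the synapse was
activated, and ``K`` is an exponential ``exp(-r/r0)`` or Gaussian
``exp(-r²/(2 r0²))`` kernel with learning length ``r0``.  The sign is
chosen so that *strengthening* pushes the network toward firing
(excitatory magnitudes grow, inhibitory magnitudes shrink) and
*weakening* does the opposite.  Weights are clamped to ``[0, ω_max]``.

The same module provides the weak-activity boost (all weights scaled
up by ``1 + α`` when the output potential never moved) and the
critical-point initialization that grows an initially weak network
until activity first reaches the output neuron.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import DynamicsConfig, TrialRecord, run_trial
from .topology import ConfigurationError, NetworkSpec

__all__ = [
    "LearningConfig",
    "InitializationError",
    "kernel_factor",
    "adapt",
    "boost_all",
    "critical_initialization",
    "STRENGTHEN",
    "WEAKEN",
]

EXPONENTIAL = "exponential"
GAUSSIAN = "gaussian"
STRENGTHEN = "strengthen"
WEAKEN = "weaken"


class InitializationError(RuntimeError):
    """Critical-point initialization failed to make the output fire."""


@dataclass(frozen=True)
class LearningConfig:
    """Adaptation parameters.

    Parameters
    ----------
    r0:
        Learning length: spatial decay scale of the adaptation signal,
        in the same length units as the network square.
    alpha:
        Adaptation strength; also the factor of the weak-activity
        boost.
    kernel:
        ``"exponential"`` or ``"gaussian"`` spatial decay.
    omega_max:
        Hard cap on every weight magnitude.
    critical_factor:
        Multiplicative growth per silent pass during critical-point
        initialization (numerically equal to ``alpha`` by default but
        conceptually distinct).
    """

    r0: float
    alpha: float = 0.001
    kernel: str = EXPONENTIAL
    omega_max: float = 2.0
    critical_factor: float = 0.001

    def __post_init__(self) -> None:
        if not self.r0 > 0:
            raise ConfigurationError("r0 must be > 0")
        if not self.alpha > 0:
            raise ConfigurationError("alpha must be > 0")
        if self.kernel not in (EXPONENTIAL, GAUSSIAN):
            raise ConfigurationError(f"unknown kernel {self.kernel!r}")
        if not self.omega_max > 0:
            raise ConfigurationError("omega_max must be > 0")
        if not self.critical_factor > 0:
            raise ConfigurationError("critical_factor must be > 0")


def kernel_factor(r, cfg: LearningConfig):
    """Spatial decay factor of the adaptation signal at distance ``r``.

    Returns a value in ``(0, 1]``; vectorized over ``r``.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("distances must be non-negative")
    if cfg.kernel == EXPONENTIAL:
        out = np.exp(-r / cfg.r0)
    else:
        out = np.exp(-(r * r) / (2.0 * cfg.r0 * cfg.r0))
    return out if out.ndim else float(out)


def _output_kernel(net: NetworkSpec, cfg: LearningConfig) -> np.ndarray:
    """Per-synapse kernel factor, measured from the output neuron to
    each postsynaptic neuron."""
    return kernel_factor(net.distances_to_output(), cfg)


def adapt(
    net: NetworkSpec,
    record: TrialRecord,
    direction: str,
    cfg: LearningConfig,
    kern: np.ndarray | None = None,
) -> NetworkSpec:
    """Apply one adaptation event for a wrong answer (in place).

    ``direction`` is ``"strengthen"`` when the target was 1 but the
    output stayed silent, ``"weaken"`` when the target was 0 but the
    output fired.  ``kern`` may carry the precomputed per-synapse
    kernel factors to avoid recomputing them every learning step.
    """
    if direction == STRENGTHEN:
        d = 1.0
    elif direction == WEAKEN:
        d = -1.0
    else:
        raise ValueError(f"direction must be strengthen/weaken, got {direction!r}")
    if kern is None:
        kern = _output_kernel(net, cfg)
    sign = np.where(net.inhibitory[net.syn_pre], -1.0, 1.0)
    factor = 1.0 + d * sign * cfg.alpha * record.n_act * kern
    np.clip(net.weights * factor, 0.0, cfg.omega_max, out=net.weights)
    return net


def boost_all(net: NetworkSpec, factor: float, omega_max: float = 2.0) -> NetworkSpec:
    """Scale every weight by ``1 + factor`` (in place), capped at
    ``omega_max``."""
    if not factor > 0:
        raise ValueError("factor must be > 0")
    np.clip(net.weights * (1.0 + factor), 0.0, omega_max, out=net.weights)
    return net


def critical_initialization(
    net: NetworkSpec,
    rule,
    dynamics_cfg: DynamicsConfig | None = None,
    learning_cfg: LearningConfig | None = None,
    max_boosts: int = 100_000,
    engine: str = "auto",
) -> tuple[NetworkSpec, int]:
    """Grow a weak network to the edge of responsiveness (in place).

    Presents the rule's inputs in order; as long as no input makes the
    output neuron fire, all weights grow by ``critical_factor`` after
    each silent pass.  Stops the first time any input fires the output:
    the network then sits close to the critical point where activity
    barely reaches the output.  Returns the network and the number of
    boosts applied.
    """
    if dynamics_cfg is None:
        dynamics_cfg = DynamicsConfig()
    if learning_cfg is None:
        learning_cfg = LearningConfig(r0=10.0)
    patterns = getattr(rule, "patterns", rule)
    boosts = 0
    while True:
        for pattern, _target in patterns:
            rec = run_trial(net, pattern, dynamics_cfg, engine=engine)
            if rec.output_fired:
                return net, boosts
        if boosts >= max_boosts:
            raise InitializationError(
                f"output never fired after {boosts} boosts; the network "
                "cannot reach the critical point under this rule"
            )
        boost_all(net, learning_cfg.critical_factor, learning_cfg.omega_max)
        boosts += 1
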