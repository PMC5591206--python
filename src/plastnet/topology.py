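"""Spatially embedded random network generation.

A network consists of four input neurons on the left edge of a square of
side ``L``, one output neuron on the right edge, and ``N`` hidden neurons
placed uniformly at random inside the square.  The square's area scales
with ``N`` so that the neuron density stays constant (``L = sqrt(N /
density)``).  Each input and hidden neuron makes ``out_degree`` directed
connections; hidden neurons wire by drawing a target distance from an
exponential distribution with scale ``d0`` and connecting to the
unconnected hidden neuron whose Euclidean distance is closest to the
draw.  Input neurons connect to their nearest hidden neighbours and the
output neuron receives connections from its nearest hidden neighbours.

Weights are magnitudes (``>= 0``); the sign of a connection is carried by
the presynaptic neuron's inhibitory flag.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np

__all__ = [
    "TopologyConfig",
    "NeuronSpec",
    "SynapseSpec",
    "NetworkSpec",
    "sample_connection_distance",
    "place_neurons",
    "wire_network",
    "initialize_weights",
    "generate_network",
]

ROLE_INPUT = 0
ROLE_HIDDEN = 1
ROLE_OUTPUT = 2
_ROLE_NAMES = {ROLE_INPUT: "input", ROLE_HIDDEN: "hidden", ROLE_OUTPUT: "output"}
_ROLE_CODES = {v: k for k, v in _ROLE_NAMES.items()}

#: weight given to synapses leaving an input neuron
INPUT_WEIGHT = 1.0
#: weight given to every other synapse
HIDDEN_WEIGHT = 0.1


class ConfigurationError(ValueError):
    """Raised for invalid topology or dynamics parameters."""


class GenerationError(RuntimeError):
    """Raised when a network cannot be wired under the given config."""


@dataclass(frozen=True)
class TopologyConfig:
    """Parameters of the spatial random network.

    Parameters
    ----------
    n_hidden:
        Number of hidden neurons ``N``.  The four input neurons and the
        single output neuron come on top of this.
    d0:
        Characteristic synaptic length: scale of the exponential
        distribution connection distances are drawn from.
    p_inh:
        Probability that a hidden neuron is inhibitory.  Input and
        output neurons are always excitatory.
    out_degree:
        Outgoing connections per input/hidden neuron, and incoming
        connections of the output neuron.
    density:
        Neurons per unit area; sets the side length ``L = sqrt(N /
        density)``.
    seed:
        Seed for the generation RNG (``None`` draws fresh entropy).
    """

    n_hidden: int
    d0: float = 2.0
    p_inh: float = 0.0
    out_degree: int = 10
    density: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_hidden < 1:
            raise ConfigurationError("n_hidden must be a positive integer")
        if not self.d0 > 0:
            raise ConfigurationError("d0 must be > 0")
        if not 0 <= self.p_inh < 1:
            raise ConfigurationError("p_inh must lie in [0, 1)")
        if not self.density > 0:
            raise ConfigurationError("density must be > 0")
        if self.out_degree < 1:
            raise ConfigurationError("out_degree must be >= 1")
        if self.out_degree > self.n_hidden - 1:
            raise ConfigurationError(
                "out_degree must not exceed n_hidden - 1 "
                f"(got {self.out_degree} with N = {self.n_hidden})"
            )

    @property
    def side_length(self) -> float:
        """Side length ``L`` of the square the network lives in."""
        return float(np.sqrt(self.n_hidden / self.density))


@dataclass(frozen=True)
class NeuronSpec:
    """A single neuron: index, position, role and sign."""

    id: int
    position: tuple[float, float]
    role: str
    is_inhibitory: bool = False


@dataclass(frozen=True)
class SynapseSpec:
    """A directed synapse; ``weight`` is a magnitude, sign lives on the
    presynaptic neuron."""

    pre: int
    post: int
    weight: float


@dataclass
class NetworkSpec:
    """A generated network in array form.

    Neurons are ordered inputs first, then hidden neurons, then the
    output neuron last.  Synapses are sorted by presynaptic index so
    that ``indptr[i]:indptr[i + 1]`` slices neuron ``i``'s outgoing
    synapses.
    """

    config: TopologyConfig
    positions: np.ndarray  # (n, 2) float64
    roles: np.ndarray  # (n,) int8, ROLE_* codes
    inhibitory: np.ndarray  # (n,) bool
    syn_pre: np.ndarray  # (m,) int32, sorted ascending
    syn_post: np.ndarray  # (m,) int32
    weights: np.ndarray  # (m,) float64 magnitudes
    indptr: np.ndarray = field(default=None)  # (n + 1,) int64

    def __post_init__(self) -> None:
        if self.indptr is None:
            counts = np.bincount(self.syn_pre, minlength=self.n_neurons)
            self.indptr = np.concatenate(([0], np.cumsum(counts)))

    # -- basic views -------------------------------------------------
    @property
    def n_neurons(self) -> int:
        return len(self.positions)

    @property
    def n_inputs(self) -> int:
        return int(np.sum(self.roles == ROLE_INPUT))

    @property
    def n_synapses(self) -> int:
        return len(self.syn_pre)

    @property
    def input_ids(self) -> np.ndarray:
        return np.flatnonzero(self.roles == ROLE_INPUT)

    @property
    def output_id(self) -> int:
        return int(np.flatnonzero(self.roles == ROLE_OUTPUT)[0])

    @property
    def hidden_ids(self) -> np.ndarray:
        return np.flatnonzero(self.roles == ROLE_HIDDEN)

    @property
    def neurons(self) -> list[NeuronSpec]:
        return [
            NeuronSpec(
                id=i,
                position=(float(self.positions[i, 0]), float(self.positions[i, 1])),
                role=_ROLE_NAMES[int(self.roles[i])],
                is_inhibitory=bool(self.inhibitory[i]),
            )
            for i in range(self.n_neurons)
        ]

    @property
    def synapses(self) -> Iterator[SynapseSpec]:
        for pre, post, w in zip(self.syn_pre, self.syn_post, self.weights):
            yield SynapseSpec(int(pre), int(post), float(w))

    def out_degrees(self) -> np.ndarray:
        return np.diff(self.indptr)

    def connection_distances(self) -> np.ndarray:
        """Euclidean length of every synapse (pre to post)."""
        d = self.positions[self.syn_pre] - self.positions[self.syn_post]
        return np.hypot(d[:, 0], d[:, 1])

    def distances_to_output(self) -> np.ndarray:
        """Per-synapse distance from the output neuron to the
        postsynaptic neuron (where the adaptation signal is sensed)."""
        d = self.positions[self.syn_post] - self.positions[self.output_id]
        return np.hypot(d[:, 0], d[:, 1])

    def copy(self) -> "NetworkSpec":
        return NetworkSpec(
            config=self.config,
            positions=self.positions.copy(),
            roles=self.roles.copy(),
            inhibitory=self.inhibitory.copy(),
            syn_pre=self.syn_pre.copy(),
            syn_post=self.syn_post.copy(),
            weights=self.weights.copy(),
            indptr=self.indptr.copy(),
        )

    # -- serialization -----------------------------------------------
    def to_dict(self) -> dict:
        cfg = {
            "n_hidden": self.config.n_hidden,
            "d0": self.config.d0,
            "p_inh": self.config.p_inh,
            "out_degree": self.config.out_degree,
            "density": self.config.density,
            "seed": self.config.seed,
        }
        neurons = [
            {
                "id": n.id,
                "x": n.position[0],
                "y": n.position[1],
                "role": n.role,
                "inhibitory": n.is_inhibitory,
            }
            for n in self.neurons
        ]
        synapses = [
            [int(p), int(q), float(w)]
            for p, q, w in zip(self.syn_pre, self.syn_post, self.weights)
        ]
        return {"config": cfg, "neurons": neurons, "synapses": synapses}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_dict(cls, doc: dict) -> "NetworkSpec":
        cfg = TopologyConfig(**doc["config"])
        neurons = sorted(doc["neurons"], key=lambda d: d["id"])
        positions = np.array([[d["x"], d["y"]] for d in neurons], dtype=float)
        roles = np.array([_ROLE_CODES[d["role"]] for d in neurons], dtype=np.int8)
        inhibitory = np.array([d["inhibitory"] for d in neurons], dtype=bool)
        syn = sorted(doc["synapses"], key=lambda s: (s[0], s[1]))
        pre = np.array([s[0] for s in syn], dtype=np.int32)
        post = np.array([s[1] for s in syn], dtype=np.int32)
        w = np.array([s[2] for s in syn], dtype=float)
        return cls(cfg, positions, roles, inhibitory, pre, post, w)

    @classmethod
    def from_json(cls, path) -> "NetworkSpec":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_graph(self):
        """Export as a :class:`networkx.DiGraph` for inspection."""
        import networkx as nx

        g = nx.DiGraph()
        for n in self.neurons:
            g.add_node(
                n.id,
                x=n.position[0],
                y=n.position[1],
                role=n.role,
                inhibitory=n.is_inhibitory,
            )
        for pre, post, w in zip(self.syn_pre, self.syn_post, self.weights):
            g.add_edge(int(pre), int(post), weight=float(w))
        return g

    def to_graphml(self, path) -> None:
        import networkx as nx

        nx.write_graphml(self.to_graph(), path)


# ---------------------------------------------------------------------
# generation operations
# ---------------------------------------------------------------------

def sample_connection_distance(d0: float, rng: np.random.Generator, size=None):
    """Draw connection distances from ``p(d) = exp(-d / d0) / d0``."""
    if not d0 > 0:
        raise ConfigurationError("d0 must be > 0")
    return rng.exponential(scale=d0, size=size)


def place_neurons(config: TopologyConfig, rng: np.random.Generator) -> NetworkSpec:
    """Place input, hidden and output neurons and assign signs.

    Input neurons sit on the left edge at ``(0, k L / 5)`` for
    ``k = 1..4``; the output neuron sits at ``(L, L / 2)``; hidden
    neurons are uniform in the square.  Only hidden neurons can be
    inhibitory (independently with probability ``p_inh``).

    Returns a :class:`NetworkSpec` with no synapses yet.
    """
    n = config.n_hidden
    L = config.side_length
    n_total = n + 5
    positions = np.empty((n_total, 2), dtype=float)
    positions[0:4, 0] = 0.0
    positions[0:4, 1] = L / 5.0 * np.arange(1, 5)
    positions[4 : 4 + n] = rng.uniform(0.0, L, size=(n, 2))
    positions[n_total - 1] = (L, L / 2.0)

    roles = np.full(n_total, ROLE_HIDDEN, dtype=np.int8)
    roles[0:4] = ROLE_INPUT
    roles[n_total - 1] = ROLE_OUTPUT

    inhibitory = np.zeros(n_total, dtype=bool)
    if config.p_inh > 0:
        inhibitory[4 : 4 + n] = rng.random(n) < config.p_inh

    empty = np.empty(0, dtype=np.int32)
    return NetworkSpec(
        config=config,
        positions=positions,
        roles=roles,
        inhibitory=inhibitory,
        syn_pre=empty,
        syn_post=empty.copy(),
        weights=np.empty(0, dtype=float),
        indptr=np.zeros(n_total + 1, dtype=np.int64),
    )


def wire_network(
    placed: NetworkSpec, config: TopologyConfig, rng: np.random.Generator
) -> NetworkSpec:
    """Create the directed synapses of a placed network.

    For every hidden neuron, ``out_degree`` target distances are drawn
    from the exponential distribution and each is resolved to the
    still-unconnected hidden neuron whose distance to the source is
    closest to the draw (deterministic nearest-to-d selection; ties go
    to the lowest index).  Input neurons connect to their ``out_degree``
    nearest hidden neurons, and the output neuron receives synapses from
    its ``out_degree`` nearest hidden neurons.  Self-loops and duplicate
    edges never occur; input neurons receive no synapses and the output
    neuron sends none.  Weights are left at zero — see
    :func:`initialize_weights`.
    """
    k = config.out_degree
    n_total = placed.n_neurons
    hidden = placed.hidden_ids
    out_id = placed.output_id
    if len(hidden) - 1 < k:
        raise GenerationError("fewer candidate targets than out_degree")

    pos = placed.positions
    pre_list: list[np.ndarray] = []
    post_list: list[np.ndarray] = []

    # input neurons -> k nearest hidden neighbours
    for i in placed.input_ids:
        d = np.hypot(*(pos[hidden] - pos[i]).T)
        nearest = hidden[np.argsort(d, kind="stable")[:k]]
        pre_list.append(np.full(k, i, dtype=np.int32))
        post_list.append(np.sort(nearest).astype(np.int32))

    # output neuron <- k nearest hidden nodes; these edges count toward
    # their source's out-degree, so the feeders draw one fewer distance
    d = np.hypot(*(pos[hidden] - pos[out_id]).T)
    nearest = hidden[np.argsort(d, kind="stable")[:k]]
    feeds_output = np.zeros(n_total, dtype=bool)
    feeds_output[nearest] = True

    # hidden neurons -> distance-sampled hidden targets
    draws = sample_connection_distance(config.d0, rng, size=(len(hidden), k))
    for row, i in enumerate(hidden):
        d = np.hypot(*(pos[hidden] - pos[i]).T)
        d[row] = np.inf  # no self-loops
        n_draws = k - 1 if feeds_output[i] else k
        targets = np.empty(n_draws + int(feeds_output[i]), dtype=np.int32)
        for j in range(n_draws):
            idx = int(np.argmin(np.abs(d - draws[row, j])))
            targets[j] = hidden[idx]
            d[idx] = np.inf  # exclude from subsequent draws of this source
        if feeds_output[i]:
            targets[-1] = out_id
        pre_list.append(np.full(len(targets), i, dtype=np.int32))
        post_list.append(np.sort(targets))

    pre = np.concatenate(pre_list)
    post = np.concatenate(post_list)
    order = np.argsort(pre, kind="stable")
    pre = pre[order]
    post = post[order]

    net = NetworkSpec(
        config=config,
        positions=pos,
        roles=placed.roles,
        inhibitory=placed.inhibitory,
        syn_pre=pre,
        syn_post=post,
        weights=np.zeros(len(pre), dtype=float),
        indptr=None,
    )
    return net


def initialize_weights(net: NetworkSpec) -> NetworkSpec:
    """Set the initial weights: 1.0 on synapses leaving input neurons,
    0.1 everywhere else (in place; also returns the network)."""
    is_input_syn = net.roles[net.syn_pre] == ROLE_INPUT
    net.weights[:] = np.where(is_input_syn, INPUT_WEIGHT, HIDDEN_WEIGHT)
    return net


def generate_network(config: TopologyConfig, seed: int | None = None) -> NetworkSpec:
    """Place, wire and weight-initialize a network in one call.

    ``seed`` overrides ``config.seed`` when given.
    """
    if seed is not None:
        config = replace(config, seed=seed)
    rng = np.random.default_rng(config.seed)
    placed = place_neurons(config, rng)
    net = wire_network(placed, config, rng)
    return initialize_weights(net)
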