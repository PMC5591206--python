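"""Supervised training loop for Boolean rules.

A rule is an ordered list of (4-bit input, target bit) pairs.  The
fifteen benchmark patterns ship as package data; most experiments train
on a contiguous prefix of them ("first3", "first10", ...).  Training
cycles through the patterns in order, resets the dynamics before every
presentation, and adapts the weights whenever the produced bit differs
from the target: strengthening when the output should have fired,
weakening when it fired spuriously, and a global weight boost when the
activity was too weak to even move the output potential.  Training
succeeds when a full cycle of consecutive presentations is answered
correctly, and fails once ``t_max`` adaptation events have been spent.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

from .dynamics import DynamicsConfig, run_trial
from .plasticity import (
    STRENGTHEN,
    WEAKEN,
    LearningConfig,
    _output_kernel,
    adapt,
    boost_all,
)
from .topology import NetworkSpec

__all__ = ["Rule", "TrainingResult", "load_rule", "train", "evaluate"]

Pattern = tuple[tuple[int, ...], int]


@dataclass(frozen=True)
class Rule:
    """An ordered Boolean input→output rule."""

    patterns: tuple[Pattern, ...]
    name: str = "rule"

    def __post_init__(self) -> None:
        if not 1 <= len(self.patterns) <= 16:
            raise ValueError("a rule must contain between 1 and 16 patterns")
        for inp, out in self.patterns:
            if any(b not in (0, 1) for b in inp) or out not in (0, 1):
                raise ValueError(f"patterns must be binary, got {(inp, out)}")

    def __len__(self) -> int:
        return len(self.patterns)

    def __iter__(self):
        return iter(self.patterns)


@dataclass
class TrainingResult:
    """Outcome of one training run."""

    learned: bool
    learning_steps: int  # adaptation events (adapt + boost) spent
    boosts: int  # weak-activity boosts among them
    history: list[tuple[int, int, int]] | None = field(default=None, repr=False)
    # history rows: (pattern index, produced bit, target bit)


def _parse_rule_lines(lines, name: str) -> Rule:
    patterns: list[Pattern] = []
    for lineno, raw in enumerate(lines, 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "->" not in line:
            raise ValueError(f"{name}:{lineno}: expected 'b b b b -> b'")
        left, right = line.split("->")
        try:
            bits = tuple(int(tok) for tok in left.split())
            target = int(right.strip())
        except ValueError as exc:
            raise ValueError(f"{name}:{lineno}: non-integer bit") from exc
        patterns.append((bits, target))
    if not patterns:
        raise ValueError(f"{name}: no patterns found")
    return Rule(tuple(patterns), name=name)


@lru_cache(maxsize=1)
def _benchmark_table() -> Rule:
    text = resources.files("plastnet").joinpath("data/table1.txt").read_text()
    return _parse_rule_lines(text.splitlines(), name="table1")


def load_rule(selector) -> Rule:
    """Resolve a rule selector.

    Accepts a :class:`Rule` (returned unchanged), an integer or a
    ``"firstK"`` / ``"all15"`` string naming a contiguous prefix of the
    embedded benchmark table, or a path to a plain-text rule file with
    one ``"b b b b -> b"`` pattern per line.
    """
    if isinstance(selector, Rule):
        return selector
    table = _benchmark_table()
    if isinstance(selector, int):
        k = selector
    elif isinstance(selector, str) and selector.startswith("first"):
        k = int(selector[len("first") :])
    elif selector in ("all", "all15"):
        k = len(table)
    elif isinstance(selector, (str, os.PathLike)) and os.path.exists(selector):
        with open(selector) as fh:
            return _parse_rule_lines(fh, name=str(selector))
    else:
        raise ValueError(f"unrecognized rule selector {selector!r}")
    if not 1 <= k <= len(table):
        raise ValueError(f"prefix length must be in 1..{len(table)}, got {k}")
    return Rule(table.patterns[:k], name=f"table1:first{k}")


def train(
    net: NetworkSpec,
    rule,
    dynamics_cfg: DynamicsConfig | None = None,
    learning_cfg: LearningConfig | None = None,
    t_max: int = 10_000,
    engine: str = "auto",
    record_history: bool = False,
) -> TrainingResult:
    """Train a critically initialized network on a rule (in place).

    Patterns are presented cyclically in table order.  Every wrong
    answer costs one learning step: a distance-weighted adaptation of
    the activated synapses, or a global boost when the output potential
    never moved.  Success is one complete cycle of consecutively
    correct answers; failure is ``t_max`` spent learning steps.
    """
    rule = load_rule(rule)
    if dynamics_cfg is None:
        dynamics_cfg = DynamicsConfig()
    if learning_cfg is None:
        learning_cfg = LearningConfig(r0=10.0)
    kern = _output_kernel(net, learning_cfg)

    n_pat = len(rule)
    history: list[tuple[int, int, int]] | None = [] if record_history else None
    steps = 0
    boosts = 0
    consecutive = 0
    idx = 0
    learned = False

    while True:
        p = idx % n_pat
        pattern, target = rule.patterns[p]
        rec = run_trial(net, pattern, dynamics_cfg, engine=engine)
        produced = rec.output_bit
        if history is not None:
            history.append((p, produced, target))
        if produced == target:
            consecutive += 1
            if consecutive >= n_pat:
                learned = True
                break
        else:
            consecutive = 0
            if steps >= t_max:
                break
            steps += 1
            if not rec.output_voltage_changed:
                boost_all(net, learning_cfg.alpha, learning_cfg.omega_max)
                boosts += 1
            else:
                direction = STRENGTHEN if target == 1 else WEAKEN
                adapt(net, rec, direction, learning_cfg, kern=kern)
        idx += 1

    return TrainingResult(
        learned=learned, learning_steps=steps, boosts=boosts, history=history
    )


def evaluate(
    net: NetworkSpec,
    rule,
    dynamics_cfg: DynamicsConfig | None = None,
    engine: str = "auto",
) -> int:
    """Count the patterns the network currently gets wrong (read-only)."""
    rule = load_rule(rule)
    if dynamics_cfg is None:
        dynamics_cfg = DynamicsConfig()
    errors = 0
    for pattern, target in rule.patterns:
        rec = run_trial(net, pattern, dynamics_cfg, engine=engine)
        if rec.output_bit != target:
            errors += 1
    return errors
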