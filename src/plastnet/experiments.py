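"""Ensemble success-rate estimation and parameter sweeps.

The learning performance of a parameter combination is summarized by
the success rate ``s``: the fraction of an ensemble of independently
generated random networks that learn every pattern of the rule within
``t_max`` learning steps.  Replicates are seeded as ``base_seed +
index`` so that results are reproducible and independent of any
parallel execution order.  Binomial uncertainty is reported as a 95%
Wilson score interval, which stays well behaved at the ``s ≈ 0`` and
``s ≈ 1`` extremes where the interesting phenomenology lives.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dynamics import DynamicsConfig
from .plasticity import LearningConfig, critical_initialization
from .topology import TopologyConfig, generate_network
from .training import load_rule, train

__all__ = [
    "CellParams",
    "SweepConfig",
    "success_rate",
    "run_sweep",
    "plot_sweep",
    "wilson_interval",
]

#: parameter names a sweep grid may vary
SWEEPABLE = (
    "n_hidden",
    "d0",
    "p_inh",
    "density",
    "out_degree",
    "r0",
    "alpha",
    "kernel",
    "omega_max",
    "t_refr",
    "activation",
    "rule",
    "t_max",
)


@dataclass(frozen=True)
class CellParams:
    """Full parameter set of one ensemble cell."""

    n_hidden: int = 1000
    d0: float = 2.0
    p_inh: float = 0.0
    density: float = 1.0
    out_degree: int = 10
    r0: float = 10.0
    alpha: float = 0.001
    kernel: str = "exponential"
    omega_max: float = 2.0
    t_refr: int = 1
    activation: str = "heaviside"
    rule: str = "first10"
    t_max: int = 10_000

    def topology(self) -> TopologyConfig:
        return TopologyConfig(
            n_hidden=self.n_hidden,
            d0=self.d0,
            p_inh=self.p_inh,
            out_degree=self.out_degree,
            density=self.density,
        )

    def dynamics(self) -> DynamicsConfig:
        return DynamicsConfig(t_refr=self.t_refr, activation=self.activation)

    def learning(self) -> LearningConfig:
        return LearningConfig(
            r0=self.r0,
            alpha=self.alpha,
            kernel=self.kernel,
            omega_max=self.omega_max,
        )


@dataclass
class SweepConfig:
    """Cartesian sweep specification.

    ``grid`` maps parameter names (see :data:`SWEEPABLE`) to value
    lists; ``base`` overrides :class:`CellParams` defaults for the
    parameters held fixed.
    """

    grid: dict = field(default_factory=dict)
    base: dict = field(default_factory=dict)
    ensemble_size: int = 20
    base_seed: int = 0
    workers: int = 1

    def __post_init__(self) -> None:
        if self.ensemble_size < 1:
            raise ValueError("ensemble_size must be >= 1")
        for key in list(self.grid) + list(self.base):
            if key not in SWEEPABLE:
                raise ValueError(f"unknown sweep parameter {key!r}")

    def cells(self) -> list[CellParams]:
        keys = sorted(self.grid)
        combos = itertools.product(*(self.grid[k] for k in keys))
        return [CellParams(**{**self.base, **dict(zip(keys, c))}) for c in combos]


def wilson_interval(successes: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """95% (by default) Wilson score interval for a binomial
    proportion."""
    from statsmodels.stats.proportion import proportion_confint

    lo, hi = proportion_confint(successes, n, alpha=1 - conf, method="wilson")
    return float(lo), float(hi)


def _run_replicate(params: CellParams, seed: int, engine: str) -> tuple[bool, int]:
    net = generate_network(params.topology(), seed=seed)
    rule = load_rule(params.rule)
    dyn = params.dynamics()
    learn = params.learning()
    critical_initialization(net, rule, dyn, learn, engine=engine)
    result = train(net, rule, dyn, learn, t_max=params.t_max, engine=engine)
    return result.learned, result.learning_steps


def success_rate(
    params: CellParams,
    ensemble_size: int = 20,
    base_seed: int = 0,
    engine: str = "auto",
) -> dict:
    """Estimate ``s`` for one parameter cell.

    Generates ``ensemble_size`` networks with seeds ``base_seed + i``,
    runs critical initialization and training on each, and returns a
    result row with the success fraction, its 95% Wilson interval, the
    mean number of learning steps among the successful replicates, and
    any per-replicate errors (recorded, not fatal).
    """
    successes = 0
    steps_ok: list[int] = []
    failures: list[str] = []
    for i in range(ensemble_size):
        try:
            learned, steps = _run_replicate(params, base_seed + i, engine)
        except Exception as exc:  # noqa: BLE001 - replicate errors are data
            failures.append(f"seed {base_seed + i}: {exc}")
            continue
        if learned:
            successes += 1
            steps_ok.append(steps)
    s = successes / ensemble_size
    lo, hi = wilson_interval(successes, ensemble_size)
    row = {
        **params.__dict__,
        "r0_over_L": params.r0 / params.topology().side_length,
        "successes": successes,
        "ensemble_size": ensemble_size,
        "s": s,
        "ci_low": lo,
        "ci_high": hi,
        "mean_steps_success": float(np.mean(steps_ok)) if steps_ok else float("nan"),
        "errors": "; ".join(failures),
    }
    return row


def run_sweep(
    cfg: SweepConfig,
    out_csv=None,
    engine: str = "auto",
    progress: bool = False,
) -> pd.DataFrame:
    """Run every cell of the sweep grid.

    Rows are written incrementally when ``out_csv`` is given; an
    existing file acts as a checkpoint and its already-computed cells
    are skipped, so an interrupted sweep resumes where it stopped.
    """
    cells = cfg.cells()
    if progress:
        from tqdm import tqdm

        cells_iter = tqdm(cells, desc="sweep")
    else:
        cells_iter = cells

    done: pd.DataFrame | None = None
    key_cols = list(CellParams().__dict__)
    if out_csv is not None:
        try:
            done = pd.read_csv(out_csv)
        except (FileNotFoundError, pd.errors.EmptyDataError):
            done = None

    rows: list[dict] = [] if done is None else done.to_dict("records")

    def _is_done(params: CellParams) -> bool:
        if done is None:
            return False
        mask = np.ones(len(done), dtype=bool)
        for k in key_cols:
            mask &= done[k].astype(str).values == str(getattr(params, k))
        return bool(mask.any())

    if cfg.workers > 1:
        from joblib import Parallel, delayed

        todo = [c for c in cells if not _is_done(c)]
        new_rows = Parallel(n_jobs=cfg.workers)(
            delayed(success_rate)(c, cfg.ensemble_size, cfg.base_seed, engine)
            for c in todo
        )
        rows.extend(new_rows)
        if out_csv is not None:
            pd.DataFrame(rows).to_csv(out_csv, index=False)
    else:
        for params in cells_iter:
            if _is_done(params):
                continue
            rows.append(success_rate(params, cfg.ensemble_size, cfg.base_seed, engine))
            if out_csv is not None:
                pd.DataFrame(rows).to_csv(out_csv, index=False)

    return pd.DataFrame(rows)


def write_manifest(cfg: SweepConfig, path) -> None:
    """Dump the full sweep configuration next to its results."""
    from . import __version__

    doc = {
        "version": __version__,
        "grid": cfg.grid,
        "base": cfg.base,
        "ensemble_size": cfg.ensemble_size,
        "base_seed": cfg.base_seed,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)


def plot_sweep(
    result: pd.DataFrame,
    x: str = "r0_over_L",
    y: str = "s",
    hue: str | None = None,
    logx: bool = True,
    path=None,
):
    """Plot success rate against a sweep axis with Wilson error bars.

    Returns the matplotlib figure; writes it to ``path`` when given.
    """
    import matplotlib.pyplot as plt

    if result.empty:
        raise ValueError("cannot plot an empty sweep result")
    for col in (x, y):
        if col not in result.columns:
            raise ValueError(f"unknown axis column {col!r}")
    fig, ax = plt.subplots(figsize=(5.2, 3.6))
    groups = [(None, result)] if hue is None else list(result.groupby(hue))
    for label, df in groups:
        df = df.sort_values(x)
        yerr = None
        if {"ci_low", "ci_high"} <= set(df.columns) and y == "s":
            yerr = np.vstack(
                (df[y].values - df["ci_low"].values, df["ci_high"].values - df[y].values)
            )
        ax.errorbar(
            df[x],
            df[y],
            yerr=yerr,
            marker="o",
            capsize=3,
            label=None if label is None else f"{hue} = {label}",
        )
    if logx:
        ax.set_xscale("log")
    ax.set_xlabel(x)
    ax.set_ylabel(y)
    ax.set_ylim(-0.05, 1.05)
    if hue is not None:
        ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
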