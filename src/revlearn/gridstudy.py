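"""Parameter-grid simulation study: how latent learning parameters map onto
conventional PRL performance measures.

Sweeps (alpha_pos, alpha_neg, pi) at a fixed inverse temperature (default
beta = 1.686), simulates many RW3 sessions per grid cell, and aggregates the
four conventional measures per cell.  Per-cell seed streams are derived from
(base_seed, cell indices), so results are independent of execution order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigError
from .metrics import session_metrics
from .models import Params
from .simulate import simulate_session
from .task import TaskConfig

MEASURES = ("n_reversals", "fraction_rewarded", "win_stay", "lose_switch")


def _default_alphas() -> tuple[float, ...]:
    return tuple(np.round(np.linspace(0.0, 1.0, 21), 10))


def _default_pis() -> tuple[float, ...]:
    return (-0.5, 0.0, 0.5, 1.0, 1.5)


@dataclass(frozen=True)
class GridSpec:
    """Specification of the simulation sweep.

    Defaults: 21 values of each learning rate on [0, 1], five stickiness
    values, beta fixed at 1.686, 50 sessions of 200 trials per cell.
    """

    alpha_pos_values: Sequence[float] = field(default_factory=_default_alphas)
    alpha_neg_values: Sequence[float] = field(default_factory=_default_alphas)
    pi_values: Sequence[float] = field(default_factory=_default_pis)
    beta_fixed: float = 1.686
    n_sims: int = 50
    n_trials: int = 200
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sims < 1:
            raise ConfigError(f"n_sims must be >= 1, got {self.n_sims}")
        for name, vals in (("alpha_pos", self.alpha_pos_values),
                           ("alpha_neg", self.alpha_neg_values)):
            if any(not (0.0 <= v <= 1.0) for v in vals):
                raise ConfigError(f"{name} values must lie in [0, 1]")


@dataclass
class SimGridResult:
    """Per-cell mean and SD of each measure over the simulations.

    ``cells`` has one row per (alpha_pos, alpha_neg, pi) cell with columns
    ``<measure>_mean`` and ``<measure>_sd``.  SDs use the sample (n-1)
    denominator and are NaN for ``n_sims == 1``; win-stay/lose-switch means
    ignore sessions where the measure is missing.
    """

    cells: pd.DataFrame
    n_sims: int
    n_trials: int
    beta_fixed: float
    base_seed: int


def _cell_seeds(base_seed: int, i: int, j: int, k: int, n: int) -> np.ndarray:
    ss = np.random.SeedSequence(entropy=base_seed, spawn_key=(i, j, k))
    return ss.generate_state(n) % (2**31)


def run_parameter_grid(grid: GridSpec) -> SimGridResult:
    """Run the sweep: n_sims RW3 sessions per cell, metrics aggregated."""
    task = TaskConfig(n_trials=grid.n_trials)
    rows = []
    for i, ap in enumerate(grid.alpha_pos_values):
        for j, an in enumerate(grid.alpha_neg_values):
            for k, pi in enumerate(grid.pi_values):
                params = Params(alpha_pos=ap, alpha_neg=an, pi=pi, beta=grid.beta_fixed)
                seeds = _cell_seeds(grid.base_seed, i, j, k, grid.n_sims)
                vals = {m: [] for m in MEASURES}
                for s in seeds:
                    met = session_metrics(simulate_session("RW3", params, task, seed=int(s)))
                    vals["n_reversals"].append(met.n_reversals)
                    vals["fraction_rewarded"].append(met.fraction_rewarded)
                    vals["win_stay"].append(np.nan if met.win_stay is None else met.win_stay)
                    vals["lose_switch"].append(np.nan if met.lose_switch is None
                                               else met.lose_switch)
                row = {"alpha_pos": ap, "alpha_neg": an, "pi": pi}
                for m in MEASURES:
                    arr = np.asarray(vals[m], dtype=float)
                    ok = ~np.isnan(arr)
                    row[f"{m}_mean"] = float(arr[ok].mean()) if ok.any() else np.nan
                    row[f"{m}_sd"] = (float(arr[ok].std(ddof=1)) if ok.sum() > 1 else np.nan)
                rows.append(row)
    cells = pd.DataFrame(rows)
    return SimGridResult(cells=cells, n_sims=grid.n_sims, n_trials=grid.n_trials,
                         beta_fixed=grid.beta_fixed, base_seed=grid.base_seed)


def percentile_region(result: SimGridResult, measure: str, q: float) -> np.ndarray:
    """Boolean mask (aligned with ``result.cells`` rows) marking cells whose
    mean of ``measure`` is at or above the q-th percentile of all cell means
    (linear-interpolation percentile; NaN cells never marked)."""
    if measure not in MEASURES:
        raise ConfigError(f"unknown measure {measure!r}; known: {', '.join(MEASURES)}")
    if not (0.0 <= q < 100.0):
        raise ConfigError(f"percentile must be in [0, 100), got {q}")
    means = result.cells[f"{measure}_mean"].to_numpy()
    threshold = np.nanpercentile(means, q)
    with np.errstate(invalid="ignore"):
        return means >= threshold


def export_grid(result: SimGridResult, path) -> pd.DataFrame:
    """Write the result as a long-format CSV: one row per (cell, measure)
    with columns alpha_pos, alpha_neg, pi, measure, mean, sd, n_sims.
    Returns the written frame."""
    records = []
    for _, row in result.cells.iterrows():
        for m in MEASURES:
            records.append({
                "alpha_pos": row["alpha_pos"], "alpha_neg": row["alpha_neg"],
                "pi": row["pi"], "measure": m,
                "mean": row[f"{m}_mean"], "sd": row[f"{m}_sd"],
                "n_sims": result.n_sims,
            })
    long = pd.DataFrame.from_records(records)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# revlearn grid beta_fixed={result.beta_fixed!r} "
                 f"n_trials={result.n_trials} base_seed={result.base_seed}\n")
        long.to_csv(fh, index=False, float_format="%.10g")
    return long


def read_grid(path) -> SimGridResult:
    """Read a long-format grid CSV back into a :class:`SimGridResult`."""
    meta: dict[str, float] = {}
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
    if first.startswith("#"):
        for token in first.lstrip("#").split():
            if "=" in token:
                key, val = token.split("=", 1)
                meta[key] = float(val)
    long = pd.read_csv(path, comment="#")
    wide_rows: dict[tuple, dict] = {}
    for _, r in long.iterrows():
        key = (r["alpha_pos"], r["alpha_neg"], r["pi"])
        row = wide_rows.setdefault(key, {"alpha_pos": key[0], "alpha_neg": key[1],
                                         "pi": key[2]})
        row[f"{r['measure']}_mean"] = r["mean"]
        row[f"{r['measure']}_sd"] = r["sd"]
    cells = pd.DataFrame(list(wide_rows.values()))
    cells = cells.astype({c: float for c in cells.columns})
    return SimGridResult(cells=cells, n_sims=int(long["n_sims"].iloc[0]),
                         n_trials=int(meta.get("n_trials", 200)),
                         beta_fixed=float(meta.get("beta_fixed", 1.686)),
                         base_seed=int(meta.get("base_seed", 0)))
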