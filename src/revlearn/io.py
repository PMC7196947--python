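"""Reading and writing sessions, fit tables and configs.

Sessions travel as plain CSV, one row per trial, columns ``session_id,
trial, choice, high_side, outcome, latency_s`` (0=left / 1=right; outcome
0=lose / 1=win; latency optional, blank allowed).  Files carry a leading
``#`` provenance comment (tool version, seed, config hash) that the readers
skip as data.  Results tables are TSV; configs are YAML or JSON.
"""

from __future__ import annotations

import hashlib
import json
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .exceptions import SchemaError
from .inference import FitResult, GridAxis, PriorSpec
from .task import Session, TaskConfig

SESSION_COLUMNS = ["session_id", "trial", "choice", "high_side", "outcome", "latency_s"]


def provenance_line(seed=None, config: Optional[str] = None) -> str:
    h = hashlib.sha1((config or "").encode()).hexdigest()[:12] if config else "none"
    return f"# revlearn {__version__} seed={seed} config_hash={h}"


def write_sessions(sessions: Sequence[Session], path, seed=None,
                   config: Optional[str] = None) -> None:
    """Write sessions as trial-per-row CSV with a provenance header.

    Floats are written at 10 significant digits; two writes of the same data
    produce byte-identical files.
    """
    rows = []
    for i, s in enumerate(sessions):
        sid = s.subject_id or f"s{i:04d}"
        lat = s.latencies
        for t in range(s.n_trials):
            rows.append({
                "session_id": sid,
                "trial": t + 1,
                "choice": int(s.choices[t]),
                "high_side": int(s.high_sides[t]),
                "outcome": int(s.outcomes[t]),
                "latency_s": (np.nan if lat is None else lat[t]),
            })
    frame = pd.DataFrame(rows, columns=SESSION_COLUMNS)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(provenance_line(seed=seed, config=config) + "\n")
        frame.to_csv(fh, index=False, float_format="%.10g")


def read_sessions(path, task: TaskConfig = TaskConfig(),
                  validate_replay: bool = True) -> list[Session]:
    """Read a session CSV, validating the schema row by row.

    Rows are grouped by ``session_id`` preserving order; trial indices must
    be contiguous 1..T within each session.  Schema violations raise
    :class:`SchemaError` citing the offending 1-based data row.  When
    ``validate_replay`` is set, the recorded high-side sequence is checked
    against a replay of the task's reversal rule.
    """
    try:
        frame = pd.read_csv(path, comment="#")
    except Exception as exc:  # noqa: BLE001 - surface parse failures as schema errors
        raise SchemaError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in SESSION_COLUMNS if c != "latency_s" and c not in frame.columns]
    if missing:
        raise SchemaError(f"missing columns: {', '.join(missing)}")
    if "latency_s" not in frame.columns:
        frame["latency_s"] = np.nan

    for col in ("choice", "high_side", "outcome"):
        bad = ~frame[col].isin((0, 1))
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
            raise SchemaError(f"column {col!r} must be 0/1; bad value on row {row}")

    sessions: list[Session] = []
    for sid, g in frame.groupby("session_id", sort=False):
        trials = g["trial"].to_numpy()
        if not np.array_equal(trials, np.arange(1, len(g) + 1)):
            row = int(g.index[0]) + 1
            raise SchemaError(
                f"session {sid!r}: trial indices must be contiguous 1..T (starts on row {row})"
            )
        lat = g["latency_s"].to_numpy(dtype=float)
        session = Session(
            choices=g["choice"].to_numpy(),
            high_sides=g["high_side"].to_numpy(),
            outcomes=g["outcome"].to_numpy(),
            task=task,
            latencies=None if np.isnan(lat).all() else lat,
            subject_id=str(sid),
        )
        if validate_replay:
            from .metrics import count_reversals
            try:
                count_reversals(session)
            except Exception as exc:
                raise SchemaError(f"session {sid!r}: {exc}") from exc
        sessions.append(session)
    return sessions


def write_table(frame: pd.DataFrame, path, sep: str = "\t", seed=None,
                config: Optional[str] = None) -> None:
    """Write a results table with a provenance comment header."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(provenance_line(seed=seed, config=config) + "\n")
        frame.to_csv(fh, sep=sep, index=False, float_format="%.10g")


def read_table(path, sep: str = "\t") -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, comment="#")


FIT_COLUMNS = ["session_id", "model", "alpha", "alpha_pos", "alpha_neg", "pi", "beta",
               "eta", "max_loglik", "loglik_at_estimate", "aic", "bic", "n_trials"]


def fits_to_frame(fits: Iterable[tuple[str, FitResult]]) -> pd.DataFrame:
    """Flatten (session_id, FitResult) pairs into one row per pair."""
    rows = []
    for sid, fr in fits:
        row = dict.fromkeys(FIT_COLUMNS, np.nan)
        row.update({"session_id": sid, "model": fr.model,
                    "max_loglik": fr.max_loglik,
                    "loglik_at_estimate": fr.loglik_at_estimate,
                    "aic": fr.aic, "bic": fr.bic, "n_trials": fr.n_trials})
        row.update(fr.estimates)
        rows.append(row)
    return pd.DataFrame(rows, columns=FIT_COLUMNS)


def load_config(path) -> dict:
    """Load a YAML or JSON config file."""
    with open(path, encoding="utf-8") as fh:
        text = fh.read()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def priors_from_config(cfg: Optional[dict]) -> PriorSpec:
    """Build a :class:`PriorSpec`, overriding default grid axes from a config
    mapping like ``{"grids": {"beta": {"lo": 0, "hi": 10, "n": 21}}}``."""
    spec = PriorSpec()
    if not cfg:
        return spec
    grids = dict(spec.grids)
    for name, g in (cfg.get("grids") or {}).items():
        grids[name] = GridAxis(float(g["lo"]), float(g["hi"]), int(g["n"]))
    return PriorSpec(grids=grids)
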