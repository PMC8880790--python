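"""Configuration handling, choice-matrix CSV round-tripping and run manifests."""

from __future__ import annotations

import dataclasses
import datetime
import json
from pathlib import Path
from typing import Dict, Mapping, Optional, Sequence

import pandas as pd
import yaml

from . import __version__
from .core import GameParams
from .simulator import ChoiceMatrix, EnsembleSummary

PARAM_KEYS = (
    "n_players",
    "n_rounds",
    "n_initial_purple",
    "p_gg",
    "p_gh",
    "p_hh",
    "value_g",
    "value_h",
    "points_per_currency",
)


def load_params(
    path: Optional[str | Path] = None, overrides: Optional[Mapping[str, object]] = None
) -> GameParams:
    """Build :class:`GameParams` from a JSON/YAML file plus overrides.

    Omitted keys take the standard defaults.  Unknown keys and constraint
    violations raise ``ValueError`` naming the offending key.
    """
    values: Dict[str, object] = {}
    if path is not None:
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() == ".json":
            loaded = json.loads(text)
        else:
            loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config {path} must contain a mapping")
        values.update(loaded)
    if overrides:
        values.update({k: v for k, v in overrides.items() if v is not None})
    unknown = set(values) - set(PARAM_KEYS)
    if unknown:
        raise ValueError(f"unknown parameter key(s): {sorted(unknown)}")
    return GameParams(**values)  # type: ignore[arg-type]


def read_choice_matrix(path: str | Path) -> ChoiceMatrix:
    """Read a choice matrix from CSV (header ``player_id,r1,...,rT``).

    Cells are restricted to ``G``/``H``; bad symbols, ragged rows and an odd
    player count raise explicit errors naming the row/column.
    """
    df = pd.read_csv(path, dtype=str)
    if df.columns[0] != "player_id":
        raise ValueError(
            f"{path}: first column must be 'player_id', got {df.columns[0]!r}"
        )
    round_cols = list(df.columns[1:])
    expected = [f"r{i + 1}" for i in range(len(round_cols))]
    if round_cols != expected:
        raise ValueError(
            f"{path}: round columns must be r1..r{len(round_cols)}, got {round_cols}"
        )
    if df.isna().any().any():
        i, c = next(
            (i, c) for c in df.columns for i in df.index if pd.isna(df.at[i, c])
        )
        raise ValueError(f"{path}: missing value at row {i + 2}, column {c!r}")
    rows = []
    for i, rec in df.iterrows():
        row = []
        for c in round_cols:
            cell = str(rec[c]).strip().upper()
            if cell not in ("G", "H"):
                raise ValueError(
                    f"{path}: invalid action {rec[c]!r} at row {i + 2}, column {c!r}"
                )
            row.append(cell == "H")
        rows.append(row)
    if len(rows) % 2 != 0:
        raise ValueError(
            f"{path}: {len(rows)} players — the population must be even "
            "(rounds pair all players)"
        )
    import numpy as np

    return ChoiceMatrix(
        is_h=np.array(rows, dtype=bool),
        player_ids=tuple(str(x) for x in df["player_id"]),
    )


def write_choice_matrix(matrix: ChoiceMatrix, path: str | Path) -> None:
    """Write a choice matrix as CSV (inverse of :func:`read_choice_matrix`)."""
    T = matrix.n_rounds
    data = {"player_id": list(matrix.player_ids)}
    for t in range(T):
        data[f"r{t + 1}"] = ["H" if h else "G" for h in matrix.is_h[:, t]]
    pd.DataFrame(data).to_csv(path, index=False)


def summary_to_frame(summary: EnsembleSummary) -> pd.DataFrame:
    """Tabulate an ensemble summary: one row per round, one lo/hi column pair
    per coverage level."""
    T = len(summary.mean_purple_by_round) - 1
    data = {
        "round": list(range(T + 1)),
        "mean_purple": summary.mean_purple_by_round,
        "median_purple": summary.median_purple_by_round,
    }
    for level, (lo, hi) in sorted(summary.bands.items()):
        tag = f"{level:g}"
        data[f"lo{tag}"] = lo
        data[f"hi{tag}"] = hi
    return pd.DataFrame(data)


def make_manifest(
    command: str,
    params: GameParams,
    seed: Optional[int] = None,
    reps: Optional[int] = None,
    strategy: Optional[Sequence[str] | str] = None,
    extra: Optional[Mapping[str, object]] = None,
) -> Dict[str, object]:
    """Metadata block reproducing a run: params, command, seed, version."""
    manifest: Dict[str, object] = {
        "command": command,
        "params": dataclasses.asdict(params),
        "seed": seed,
        "reps": reps,
        "strategy": strategy,
        "version": __version__,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    if extra:
        manifest.update(extra)
    return manifest


def write_json(obj: object, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonable) + "\n")


def _jsonable(o: object):
    import numpy as np

    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.integer, np.floating)):
        return o.item()
    raise TypeError(f"not JSON serializable: {type(o)}")
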