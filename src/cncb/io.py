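"""Reading and writing trial tables, counts and result files.

All files are plain delimited text (CSV) or structured text (YAML/JSON):
the package has no binary formats.  Trial tables carry one row per trial
with columns ``stimulus`` (strength), ``response`` (-1/+1; 0/1 is
accepted and recoded) and ``confidence`` (integer level) or
``confidence_cont`` (real in (0, 1)).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, is_dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data import RatingCounts, trials_to_counts

__all__ = ["read_trials", "write_trials", "read_counts", "write_result",
           "write_metadata", "read_metadata"]

log = logging.getLogger("cncb")


def read_trials(path, m: int | None = None) -> pd.DataFrame:
    """Read and validate a delimited trial table.

    Responses coded {0, 1} are recoded to {-1, +1} (with a logged note);
    rows with missing values, unknown response codes or out-of-range
    confidence levels raise a parse error listing the offending rows.
    """
    df = pd.read_csv(path)
    if "stimulus" not in df.columns or "response" not in df.columns:
        raise ValueError(f"{path}: trial tables need 'stimulus' and 'response' columns")
    has_disc = "confidence" in df.columns
    has_cont = "confidence_cont" in df.columns
    if not (has_disc or has_cont):
        raise ValueError(f"{path}: need a 'confidence' or 'confidence_cont' column")
    bad = df.index[df.isna().any(axis=1)].tolist()
    if bad:
        raise ValueError(f"{path}: missing values in rows {bad[:20]}")
    resp = df["response"].to_numpy()
    if set(np.unique(resp)).issubset({0, 1}):
        log.info("responses coded 0/1; recoding to -1/+1")
        df["response"] = np.where(resp > 0, 1, -1)
    elif not set(np.unique(resp)).issubset({-1, 1}):
        bad = df.index[~df["response"].isin([-1, 1])].tolist()
        raise ValueError(f"{path}: unknown response codes in rows {bad[:20]}")
    if has_disc:
        lev = df["confidence"].to_numpy()
        if np.any(lev != np.round(lev)):
            bad = df.index[lev != np.round(lev)].tolist()
            raise ValueError(f"{path}: non-integer confidence in rows {bad[:20]}")
        df["confidence"] = lev.astype(int)
        m_eff = m or int(df["confidence"].max())
        out = df.index[(df["confidence"] < 1) | (df["confidence"] > m_eff)].tolist()
        if out:
            raise ValueError(
                f"{path}: confidence outside 1..{m_eff} in rows {out[:20]}"
            )
    if has_cont:
        r = df["confidence_cont"].to_numpy(float)
        if r.max() > 1.0 and r.max() <= 100.0:
            log.info("continuous confidence on a 0-100 scale; rescaling to (0,1)")
            r = r / 100.0
        out = df.index[(r < 0) | (r > 1)].tolist()
        if out:
            raise ValueError(f"{path}: confidence_cont outside [0,1] in rows {out[:20]}")
        df["confidence_cont"] = np.clip(r, 1e-4, 1 - 1e-4)
    return df


def write_trials(trials: pd.DataFrame, path) -> None:
    """Write a trial table as CSV (no index column)."""
    cols = [c for c in ("stimulus", "response", "confidence", "confidence_cont")
            if c in trials.columns]
    trials[cols].to_csv(path, index=False)


def read_counts(path, m: int | None = None,
                mu: np.ndarray | None = None) -> RatingCounts:
    """Read a trial table and aggregate it to a count tensor."""
    return trials_to_counts(read_trials(path, m=m), m=m, mu=mu)


def _jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(asdict(obj))
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def write_result(result, path, config: dict | None = None) -> None:
    """Serialize a result object (fit, efficiency, ...) as JSON with the
    run configuration embedded, so every output is self-describing."""
    payload = {"result": _jsonable(result)}
    if config is not None:
        payload["config"] = _jsonable(config)
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")


def write_metadata(meta: dict, path) -> None:
    """YAML sidecar with simulation parameters and seed."""
    Path(path).write_text(yaml.safe_dump(_jsonable(meta), sort_keys=False))


def read_metadata(path) -> dict:
    return yaml.safe_load(Path(path).read_text())
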