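"""Session-table and result serialization.

Sessions are exchanged as UTF-8 comma-separated text with a mandatory
header, one row per trial attempt, columns exactly matching the trial
record fields (plus session and subject identifiers so several sessions
can share a file).  Missing reaction times are empty fields.  Fitted
objects are serialized as JSON; value tables as CSV keyed by
(NTk, TSCO, TE, NObs).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .task import SessionData, TrialRecord

__all__ = ["SESSION_COLUMNS", "read_sessions", "write_sessions", "write_results"]

SESSION_COLUMNS = [
    "session_id",
    "subject_id",
    "block",
    "trial",
    "attempt",
    "condition",
    "side_first_left",
    "choice",
    "delivered",
    "delta_tokens",
    "tokens_before",
    "tokens_after",
    "tsco",
    "cashout",
    "juice_drops",
    "rt_fix",
    "rt_choice",
    "abort_code",
]


def write_sessions(sessions: Sequence[SessionData], path) -> None:
    rows = []
    for s in sessions:
        for r in s.records:
            d = dataclasses.asdict(r)
            d["session_id"] = s.session_id
            d["subject_id"] = s.subject_id
            rows.append(d)
    df = pd.DataFrame(rows, columns=SESSION_COLUMNS)
    df["choice"] = df["choice"].astype("Int64")
    df.to_csv(path, index=False, float_format="%.17g")


def read_sessions(path) -> list[SessionData]:
    """Read a session table, schema-checked; round-trips ``write_sessions``."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in SESSION_COLUMNS if c not in df.columns]
    extra = [c for c in df.columns if c not in SESSION_COLUMNS]
    if missing or extra:
        raise ValueError(
            f"session table schema error: missing={missing}, unexpected={extra}"
        )
    for col in ("block", "trial", "attempt", "condition", "tokens_before",
                "tokens_after", "tsco", "juice_drops", "delta_tokens"):
        bad = df[col].isna()
        if bad.any():
            raise ValueError(
                f"malformed numeric field {col!r} at rows {list(df.index[bad][:5])}"
            )
    sessions = []
    for (sid, sub), grp in df.groupby(["session_id", "subject_id"], sort=False):
        records = []
        for _, row in grp.iterrows():
            records.append(
                TrialRecord(
                    block=int(row["block"]),
                    trial=int(row["trial"]),
                    attempt=int(row["attempt"]),
                    condition=int(row["condition"]),
                    side_first_left=bool(row["side_first_left"]),
                    choice=None if pd.isna(row["choice"]) else int(row["choice"]),
                    delivered=bool(row["delivered"]),
                    delta_tokens=int(row["delta_tokens"]),
                    tokens_before=int(row["tokens_before"]),
                    tokens_after=int(row["tokens_after"]),
                    tsco=int(row["tsco"]),
                    cashout=bool(row["cashout"]),
                    juice_drops=int(row["juice_drops"]),
                    rt_fix=None if pd.isna(row["rt_fix"]) else float(row["rt_fix"]),
                    rt_choice=None
                    if pd.isna(row["rt_choice"])
                    else float(row["rt_choice"]),
                    abort_code=str(row["abort_code"]),
                )
            )
        sessions.append(SessionData(records=records, session_id=str(sid), subject_id=str(sub)))
    return sessions


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return dataclasses.asdict(obj)
        return super().default(obj)


def write_results(obj, path) -> None:
    """Serialize fitted objects (dataclasses, arrays, dicts) as JSON."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, cls=_NumpyEncoder)
        fh.write("\n")
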