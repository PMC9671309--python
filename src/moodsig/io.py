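"""Readers and writers for the cohort CSV formats.

Two dialects are supported (UTF-8, header row, '.' decimal):

* wide — one row per participant-week:
  ``participant_id,week,asrm,qids,eq5d,gad7[,diagnosis]``
* long — one row per response:
  ``participant_id,date,instrument,score[,diagnosis]``

The sentinel ``-1`` marks missing responses and is preserved on read.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .encoding import CLASSES, DEFAULT_RANGES, INSTRUMENTS, SENTINEL, MoodStream
from .preprocess import align_weekly

logger = logging.getLogger(__name__)

WIDE_COLUMNS = ["participant_id", "week", *INSTRUMENTS]


def read_cohort(
    path: str | Path,
    schema: str = "wide",
    ranges: dict[str, float] | None = None,
    sentinel: float = SENTINEL,
) -> list[MoodStream]:
    """Read and validate a cohort CSV into per-participant weekly streams.

    Out-of-range (non-sentinel) scores and unknown diagnosis labels are
    reported with their offending rows.  An empty file yields an empty cohort
    with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    if df.empty:
        logger.warning("%s is empty; returning an empty cohort", path)
        return []
    if schema == "long":
        return align_weekly(df, sentinel=sentinel)
    if schema != "wide":
        raise ValueError(f"unknown schema {schema!r}")
    missing_cols = set(WIDE_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValueError(f"{path}: missing columns {sorted(missing_cols)}")
    ranges = ranges or DEFAULT_RANGES
    offenders = []
    for name in INSTRUMENTS:
        col = df[name].astype(float)
        bad = (col != sentinel) & ((col < 0) | (col > ranges[name]))
        for i in df.index[bad]:
            offenders.append(f"row {i + 2}: {name}={col[i]} outside [0, {ranges[name]}]")
    if offenders:
        raise ValueError(f"{path}: out-of-range scores:\n" + "\n".join(offenders[:20]))
    if "diagnosis" in df.columns:
        unknown = set(df["diagnosis"].dropna().unique()) - set(CLASSES)
        if unknown:
            raise ValueError(f"{path}: unknown diagnosis label(s) {sorted(unknown)}")
    streams = []
    for pid, grp in df.groupby("participant_id", sort=True):
        grp = grp.sort_values("week")
        diagnosis = None
        if "diagnosis" in grp.columns and grp["diagnosis"].notna().any():
            diagnosis = str(grp["diagnosis"].dropna().iloc[0])
        weeks = grp["week"].to_numpy(dtype=int)
        streams.append(
            MoodStream(
                participant_id=str(pid),
                weeks=weeks - weeks[0] if weeks.size else weeks,
                scores=grp[list(INSTRUMENTS)].to_numpy(dtype=float),
                diagnosis=diagnosis,
                sentinel=sentinel,
            )
        )
    return streams


def write_cohort(streams: Sequence[MoodStream], path: str | Path) -> None:
    """Write streams as wide-format CSV (round-trips through read_cohort)."""
    rows = []
    for s in streams:
        for t in range(s.n_weeks):
            row = {
                "participant_id": s.participant_id,
                "week": int(s.weeks[t]),
            }
            for c, name in enumerate(INSTRUMENTS):
                v = s.scores[t, c]
                row[name] = int(v) if float(v).is_integer() else v
            if s.diagnosis is not None:
                row["diagnosis"] = s.diagnosis
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
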