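"""Weekly alignment, exclusions, scale-free normalisation and ten-week windows.

The raw questionnaire table (one row per response) is aligned on calendar
weeks, with only the first response of a week kept; weeks without a response
get the missing sentinel.  Participants with fewer than ten task-active weeks
are excluded.  After missingness encoding, each channel is normalised by its
maximum attainable value and accumulated (cumulative sum, with an origin
basepoint) so the path is scale-free, then cut into overlapping ten-week
sliding windows which are re-based to start at the origin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .encoding import (
    DEFAULT_RANGES,
    INSTRUMENTS,
    SENTINEL,
    EncodedStream,
    MoodStream,
    encode_missing,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry: width (weeks) and stride (weeks).

    The default ten-week width with unit stride gives ``W - 9`` overlapping
    windows per participant with W weeks of data.
    """

    width: int = 10
    stride: int = 1

    def __post_init__(self):
        if self.width < 2:
            raise ValueError("window width must be >= 2 weeks")
        if self.stride < 1:
            raise ValueError("window stride must be >= 1 week")


@dataclass
class PreparedWindow:
    """A (width+1, C+1)-point path ready for log-signature extraction.

    The path starts at the origin and each channel is a cumulative sum of
    normalised weekly values (scores scaled to [0, 1] by instrument range;
    the miss-count channel scaled by its maximum possible window total).
    """

    path: np.ndarray
    participant_id: str
    diagnosis: Optional[str]
    start_week: int


def align_weekly(
    raw_rows: pd.DataFrame,
    instruments: Sequence[str] = INSTRUMENTS,
    diagnosis_col: str = "diagnosis",
    sentinel: float = SENTINEL,
) -> list[MoodStream]:
    """Align a long-format response table into per-participant weekly streams.

    ``raw_rows`` needs columns ``participant_id, date, instrument, score`` and
    optionally a per-participant diagnosis column.  Rows are bucketed by ISO
    calendar week; exact duplicates are dropped and, when several responses to
    the same instrument fall in one week, only the earliest is kept.  Weeks
    between a participant's first and last response with no response are filled
    with the sentinel.
    """
    df = raw_rows.copy()
    required = {"participant_id", "date", "instrument", "score"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise ValueError(f"missing required columns: {sorted(missing_cols)}")
    unknown = set(df["instrument"]) - set(instruments)
    if unknown:
        raise ValueError(f"unknown instrument name(s): {sorted(unknown)}")
    df["date"] = pd.to_datetime(df["date"])
    df = df.drop_duplicates()
    df = df.sort_values(["participant_id", "date"], kind="stable")
    iso = df["date"].dt.isocalendar()
    # Continuous week index: ISO year * 53 + ISO week is monotone across years
    # for ordering; differences are later re-based per participant.
    df["_week"] = (iso["year"].astype(int) - 1970) * 53 + iso["week"].astype(int)

    streams: list[MoodStream] = []
    for pid, grp in df.groupby("participant_id", sort=True):
        first = grp.drop_duplicates(subset=["_week", "instrument"], keep="first")
        w0, w1 = int(grp["_week"].min()), int(grp["_week"].max())
        weeks = np.arange(w0, w1 + 1)
        scores = np.full((weeks.size, len(instruments)), sentinel, dtype=float)
        col_of = {name: c for c, name in enumerate(instruments)}
        for _, row in first.iterrows():
            scores[int(row["_week"]) - w0, col_of[row["instrument"]]] = row["score"]
        diagnosis = None
        if diagnosis_col in grp.columns:
            labels = grp[diagnosis_col].dropna().unique()
            if len(labels) > 1:
                raise ValueError(f"participant {pid} has conflicting diagnoses {labels}")
            if len(labels) == 1:
                diagnosis = str(labels[0])
        streams.append(
            MoodStream(
                participant_id=str(pid),
                weeks=np.arange(weeks.size),
                scores=scores,
                diagnosis=diagnosis,
                sentinel=sentinel,
            )
        )
    return streams


def apply_exclusions(
    streams: Iterable[MoodStream], min_weeks: int = 10
) -> list[MoodStream]:
    """Drop participants with fewer than ``min_weeks`` task-active weeks."""
    if min_weeks < 1:
        raise ValueError("min_weeks must be >= 1")
    streams = list(streams)
    kept = [s for s in streams if s.n_weeks >= min_weeks]
    n_dropped = len(streams) - len(kept)
    if n_dropped:
        logger.info(
            "excluded %d of %d participants with fewer than %d weeks",
            n_dropped, len(streams), min_weeks,
        )
    if not kept:
        logger.warning("cohort is empty after exclusions")
    return kept


def normalize_accumulate(
    encoded: EncodedStream,
    ranges: dict[str, float] | None = None,
    width: int = 10,
) -> tuple[np.ndarray, np.ndarray]:
    """Scale-free transform of an encoded stream.

    Returns ``(weekly, path)`` where ``weekly`` is the (W, C+1) matrix of
    normalised weekly values — score channel ``c`` divided by its range and the
    weekly miss-count increments divided by ``C * width`` (the maximum total a
    window of ``width`` weeks could accumulate) — and ``path`` is its
    (W+1, C+1) cumulative sum with the origin prepended.
    """
    ranges = ranges or DEFAULT_RANGES
    C = encoded.n_channels
    names = INSTRUMENTS[:C]
    divisors = np.array([ranges[n] for n in names], dtype=float)
    if np.any(divisors <= 0):
        raise ValueError("instrument ranges must be strictly positive")
    too_big = encoded.filled > divisors
    if np.any(too_big):
        t, c = np.argwhere(too_big)[0]
        raise ValueError(
            f"participant {encoded.participant_id}, week {int(encoded.weeks[t])}, "
            f"channel {names[c]}: value {encoded.filled[t, c]} exceeds range "
            f"{divisors[c]}"
        )
    scores = encoded.filled / divisors
    counts = np.atleast_2d(encoded.miss_count.T).T.astype(float)
    increments = np.diff(np.vstack([np.zeros((1, counts.shape[1])), counts]), axis=0)
    miss = increments / (C * width)
    weekly = np.hstack([scores, miss])
    path = np.vstack([np.zeros((1, weekly.shape[1])), np.cumsum(weekly, axis=0)])
    return weekly, path


def cut_windows(
    weekly: np.ndarray,
    spec: WindowSpec,
    participant_id: str,
    diagnosis: Optional[str] = None,
) -> list[PreparedWindow]:
    """Cut normalised weekly values into re-based sliding-window paths.

    Each window covers ``spec.width`` consecutive weeks; its path is the
    cumulative sum of the window's weekly values with the origin prepended, so
    every window starts at zero regardless of its position in the stream.
    Returns ``floor((W - width) / stride) + 1`` windows, or an empty list (with
    a warning) when the stream is shorter than one window.
    """
    W = weekly.shape[0]
    if W < spec.width:
        logger.warning(
            "participant %s: %d weeks < window width %d; no windows",
            participant_id, W, spec.width,
        )
        return []
    windows = []
    for start in range(0, W - spec.width + 1, spec.stride):
        chunk = weekly[start : start + spec.width]
        path = np.vstack([np.zeros((1, chunk.shape[1])), np.cumsum(chunk, axis=0)])
        windows.append(
            PreparedWindow(
                path=path,
                participant_id=participant_id,
                diagnosis=diagnosis,
                start_week=start,
            )
        )
    return windows


def prepare_cohort(
    streams: Iterable[MoodStream],
    spec: WindowSpec = WindowSpec(),
    ranges: dict[str, float] | None = None,
    per_channel_counts: bool = False,
) -> list[PreparedWindow]:
    """Full preprocessing: encode missingness on each full stream, normalise
    and accumulate, then cut sliding windows.

    Missingness is encoded before windowing so the count context spans the
    whole stream; windows are re-based afterwards so their paths all start at
    the origin and are translation-comparable.
    """
    out: list[PreparedWindow] = []
    for stream in streams:
        stream.validate_ranges(ranges)
        encoded = encode_missing(stream, per_channel=per_channel_counts)
        weekly, _ = normalize_accumulate(encoded, ranges=ranges, width=spec.width)
        out.extend(cut_windows(weekly, spec, stream.participant_id, stream.diagnosis))
    return out
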