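"""Missing-response encoding: feed-forward fill plus a cumulative miss-count channel.

A missing weekly response (sentinel ``-1`` by default) is not imputed.  Instead
it is (a) replaced by the most recent prior valid value in the same channel, so
the filled score stream carries zero increment over missing weeks, and (b)
counted in an extra cumulative channel, so the *timing and amount* of
missingness enters the path as its own signal.  This keeps the increments of
both the observed scores and the missing counts, which is what the downstream
log-signature features respond to.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: The three diagnostic groups, in the fixed order used everywhere downstream.
CLASSES = ("BD", "HC", "BPD")

#: Instrument channels, in column order.
INSTRUMENTS = ("asrm", "qids", "eq5d", "gad7")

#: Score maxima used for range validation and scale-free normalisation.
#: QIDS runs 0-27, GAD-7 0-21 and EQ-5D 0-100 per the instruments' definitions;
#: ASRM's five items score 0-4 each, giving a 0-20 range.
DEFAULT_RANGES = {"asrm": 20.0, "qids": 27.0, "eq5d": 100.0, "gad7": 21.0}

SENTINEL = -1.0


@dataclass
class MoodStream:
    """One participant's weekly multi-channel score sequence.

    ``scores`` is a (W, C) array over consecutive weeks; the sentinel value
    marks a missing response.  ``diagnosis`` may be None for unlabeled data.
    """

    participant_id: str
    weeks: np.ndarray
    scores: np.ndarray
    diagnosis: Optional[str] = None
    sentinel: float = SENTINEL

    def __post_init__(self):
        self.weeks = np.asarray(self.weeks, dtype=int)
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[0] != self.weeks.size:
            raise ValueError("scores must be a (W, C) matrix matching weeks")
        if self.weeks.size and np.any(np.diff(self.weeks) != 1):
            raise ValueError(
                f"participant {self.participant_id}: week indices must be "
                "consecutive integers"
            )
        if self.diagnosis is not None and self.diagnosis not in CLASSES:
            raise ValueError(f"unknown diagnosis label {self.diagnosis!r}")

    @property
    def n_weeks(self) -> int:
        return int(self.weeks.size)

    @property
    def missing_mask(self) -> np.ndarray:
        return self.scores == self.sentinel

    def validate_ranges(self, ranges: dict[str, float] | None = None) -> None:
        """Raise if any non-sentinel score falls outside its instrument range."""
        ranges = ranges or DEFAULT_RANGES
        for c, name in enumerate(INSTRUMENTS[: self.scores.shape[1]]):
            col = self.scores[:, c]
            valid = col != self.sentinel
            bad = valid & ((col < 0) | (col > ranges[name]))
            if np.any(bad):
                week = int(self.weeks[np.argmax(bad)])
                raise ValueError(
                    f"participant {self.participant_id}, week {week}, channel "
                    f"{name}: score {col[np.argmax(bad)]} outside [0, {ranges[name]}]"
                )


@dataclass
class EncodedStream:
    """A complete (sentinel-free) score stream with its cumulative miss count.

    ``miss_count[t]`` is the total number of missing entries over all channels
    in weeks up to and including ``t``; it is non-decreasing and ends at the
    stream's total sentinel count.  With ``per_channel`` counting, ``miss_count``
    is (W, C) instead and each column counts one channel's misses.
    """

    participant_id: str
    weeks: np.ndarray
    filled: np.ndarray
    miss_count: np.ndarray
    diagnosis: Optional[str] = None
    n_channels: int = field(init=False)

    def __post_init__(self):
        self.n_channels = self.filled.shape[1]


def _feed_forward(col: np.ndarray, mask: np.ndarray, who: str, channel: int) -> np.ndarray:
    """Fill masked entries with the nearest prior valid value; leading missing
    entries are back-filled with the first subsequent valid value."""
    if mask.all():
        raise ValueError(
            f"participant {who}, channel {channel}: every week is missing; "
            "no valid value exists to fill from"
        )
    out = col.copy()
    valid_idx = np.flatnonzero(~mask)
    # np.maximum.accumulate trick: index of most recent valid position
    last_valid = np.where(~mask, np.arange(col.size), -1)
    last_valid = np.maximum.accumulate(last_valid)
    lead = last_valid < 0
    out[~lead] = col[last_valid[~lead]]
    out[lead] = col[valid_idx[0]]
    return out


def encode_missing(
    stream: MoodStream, per_channel: bool = False
) -> EncodedStream:
    """Encode a stream's missing responses per the feed-forward + count scheme.

    Each sentinel entry is replaced by the most recent prior valid value of the
    same channel (leading sentinels are back-filled from the first valid value),
    and ``miss_count`` accumulates the number of missing entries week by week.
    A stream with no sentinels comes back value-identical with an all-zero
    count.
    """
    if stream.n_weeks < 1:
        raise ValueError("stream must contain at least one week")
    mask = stream.missing_mask
    filled = stream.scores.copy()
    for c in range(filled.shape[1]):
        if mask[:, c].any():
            filled[:, c] = _feed_forward(
                stream.scores[:, c], mask[:, c], stream.participant_id, c
            )
    if per_channel:
        miss_count = np.cumsum(mask.astype(int), axis=0)
    else:
        miss_count = np.cumsum(mask.sum(axis=1).astype(int))
    return EncodedStream(
        participant_id=stream.participant_id,
        weeks=stream.weeks.copy(),
        filled=filled,
        miss_count=miss_count,
        diagnosis=stream.diagnosis,
    )
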