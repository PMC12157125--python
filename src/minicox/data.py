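"""Survival-data containers and delimited-text I/O.

A subject in a right-censored study is summarised by the observed time
``T* = min(T, C)`` (event time ``T``, censoring time ``C``), the event
indicator ``δ`` (1 if the event was observed, 0 if censoring cut the
follow-up short) and, for the two-task setting, an optional binary disease
label ``y``.  Times are plain numeric durations in arbitrary units; no
calendar handling is done here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = ["SurvivalRecord", "SurvivalDataset"]


@dataclass(frozen=True)
class SurvivalRecord:
    """One subject: observed time, event indicator, optional disease label."""

    time: float
    event: int
    label: Optional[int] = None
    sample_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.time) or self.time <= 0:
            raise ValueError(f"time must be positive and finite, got {self.time}")
        if self.event not in (0, 1):
            raise ValueError(f"event indicator must be 0 or 1, got {self.event}")
        if self.label is not None and self.label not in (0, 1):
            raise ValueError(f"label must be 0, 1 or None, got {self.label}")


class SurvivalDataset:
    """An ordered collection of right-censored survival records.

    Internally stored as aligned numpy arrays (``times``, ``events``,
    ``labels``, ``sample_ids``) so losses and metrics vectorise; the
    record view is available through :meth:`records`.
    """

    def __init__(
        self,
        times: Sequence[float],
        events: Sequence[int],
        labels: Optional[Sequence[int]] = None,
        sample_ids: Optional[Sequence[str]] = None,
    ) -> None:
        self.times = np.asarray(times, dtype=float)
        self.events = np.asarray(events, dtype=int)
        if self.times.ndim != 1 or self.times.size < 1:
            raise ValueError("dataset needs at least one record")
        if self.times.shape != self.events.shape:
            raise ValueError("times and events must be aligned")
        if np.any(~np.isfinite(self.times)) or np.any(self.times <= 0):
            raise ValueError("all observed times must be positive and finite")
        if not np.isin(self.events, (0, 1)).all():
            raise ValueError("event indicators must be 0 or 1")
        if labels is None:
            self.labels = None
        else:
            self.labels = np.asarray(labels, dtype=int)
            if self.labels.shape != self.times.shape:
                raise ValueError("labels must be aligned with times")
            if not np.isin(self.labels, (0, 1)).all():
                raise ValueError("labels must be 0 or 1")
        if sample_ids is None:
            self.sample_ids = np.array([f"s{i}" for i in range(self.times.size)])
        else:
            self.sample_ids = np.asarray(sample_ids, dtype=object)
            if self.sample_ids.shape != self.times.shape:
                raise ValueError("sample_ids must be aligned with times")
        if len(set(self.sample_ids)) != self.times.size:
            raise ValueError("sample_ids must be unique")

    # -- basic protocol -------------------------------------------------
    @property
    def n(self) -> int:
        return int(self.times.size)

    def __len__(self) -> int:
        return self.n

    def records(self) -> list[SurvivalRecord]:
        labels = self.labels if self.labels is not None else [None] * self.n
        return [
            SurvivalRecord(t, int(e), None if l is None else int(l), str(s))
            for t, e, l, s in zip(self.times, self.events, labels, self.sample_ids)
        ]

    @classmethod
    def from_records(cls, records: Iterable[SurvivalRecord]) -> "SurvivalDataset":
        records = list(records)
        labels = [r.label for r in records]
        has_labels = any(l is not None for l in labels)
        if has_labels and any(l is None for l in labels):
            raise ValueError("either all or no records may carry a label")
        return cls(
            times=[r.time for r in records],
            events=[r.event for r in records],
            labels=labels if has_labels else None,
            sample_ids=[
                r.sample_id if r.sample_id is not None else f"s{i}"
                for i, r in enumerate(records)
            ],
        )

    def subset(self, indices: Sequence[int]) -> "SurvivalDataset":
        idx = np.asarray(indices, dtype=int)
        return SurvivalDataset(
            self.times[idx],
            self.events[idx],
            None if self.labels is None else self.labels[idx],
            self.sample_ids[idx],
        )

    # -- delimited-text interface ---------------------------------------
    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            {"sample_id": self.sample_ids, "time": self.times, "event": self.events}
        )
        if self.labels is not None:
            frame["label"] = self.labels
        return frame

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "SurvivalDataset":
        required = {"sample_id", "time", "event"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"survival table is missing columns: {sorted(missing)}")
        return cls(
            times=frame["time"].to_numpy(float),
            events=frame["event"].to_numpy(int),
            labels=frame["label"].to_numpy(int) if "label" in frame.columns else None,
            sample_ids=frame["sample_id"].astype(str).to_numpy(object),
        )

    @classmethod
    def read_csv(cls, path) -> "SurvivalDataset":
        return cls.from_frame(pd.read_csv(path))
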