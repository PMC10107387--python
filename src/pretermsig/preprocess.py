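"""Record preprocessing: epoch averaging, length down-selection, windowing.

Acquisition-scale signals (e.g. 900 Hz EHG) are reduced to an envelope by
non-overlapping 2-s epoch averaging of the absolute amplitude. Each
retained record is then split into 10 equal, disjoint, contiguous windows;
the trailing remainder (N mod n_windows samples) is dropped so the windows
have identical length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .synth import Record

__all__ = ["WindowSet", "epoch_average", "select_records", "window_disjoint"]

logger = logging.getLogger(__name__)


@dataclass
class WindowSet:
    """The equal disjoint slices of one record, with its label carried along."""

    record_ref: str
    label: str
    windows: list[np.ndarray]
    fs: float | None = None
    signal_kind: str = "EHG"

    def __post_init__(self) -> None:
        lengths = {len(w) for w in self.windows}
        if len(lengths) > 1:
            raise ValueError("windows must all have equal length")

    @property
    def n_windows(self) -> int:
        return len(self.windows)


def epoch_average(raw: Record, epoch_s: float = 2.0, mode: str = "mean_abs") -> Record:
    """Collapse each non-overlapping ``epoch_s``-second block to one sample.

    ``mean_abs`` (default) averages the absolute amplitude, producing the
    contraction envelope; ``rms`` is available as an alternative envelope
    definition. Output sampling rate is 1/epoch_s; a trailing partial epoch
    is dropped.
    """
    if raw.fs is None or raw.fs <= 0:
        raise ValueError("record must have a positive sampling rate")
    n_per = int(round(epoch_s * raw.fs))
    if n_per < 1:
        raise ValueError("epoch_s * fs must be >= 1 sample")
    n_epochs = len(raw) // n_per
    if n_epochs == 0:
        raise ValueError("record shorter than one epoch")
    blocks = np.abs(raw.samples[: n_epochs * n_per]).reshape(n_epochs, n_per)
    if mode == "mean_abs":
        env = blocks.mean(axis=1)
    elif mode == "rms":
        env = np.sqrt((blocks**2).mean(axis=1))
    else:
        raise ValueError(f"unknown envelope mode {mode!r}")
    return Record(raw.patient_id, raw.label, raw.signal_kind, env, fs=1.0 / epoch_s)


def select_records(cohort: list[Record], min_len: int) -> list[Record]:
    """Keep records with at least ``min_len`` samples, preserving order."""
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    kept, excluded = [], []
    for rec in cohort:
        (kept if len(rec) >= min_len else excluded).append(rec)
    if excluded:
        logger.warning(
            "down-selection excluded %d record(s): %s",
            len(excluded), [r.patient_id for r in excluded],
        )
    if not kept:
        logger.warning("no records survive min_len=%d", min_len)
    return kept


def window_disjoint(record: Record, n_windows: int = 10) -> WindowSet:
    """Split a record into ``n_windows`` equal contiguous disjoint windows.

    Each window holds floor(N / n_windows) samples; the remainder at the
    tail is discarded.
    """
    n = len(record)
    if n < n_windows:
        raise ValueError(
            f"record {record.patient_id} has {n} samples, fewer than "
            f"{n_windows} windows"
        )
    width = n // n_windows
    windows = [
        record.samples[i * width : (i + 1) * width].copy() for i in range(n_windows)
    ]
    return WindowSet(
        record_ref=record.patient_id,
        label=record.label,
        windows=windows,
        fs=record.fs,
        signal_kind=record.signal_kind,
    )
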