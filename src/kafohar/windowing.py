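"""Segmenting labeled recordings into fixed-length overlapping windows.

Windows are anchored per label interval: the slider restarts at each
interval's first sample and never crosses into a neighbouring interval or an
unlabeled gap, so every window carries exactly one activity label. With the
default 6 s windows at 75% overlap on 30 Hz data, each window is a 3x180
matrix and the stride is 45 samples (1.5 s). Partial trailing windows are
dropped; within an interval holding D seconds of samples the window count is
floor((D - window_s) / stride_s) + 1 when D >= window_s, else 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .io import Cohort, Recording, ValidationError

DEFAULT_WINDOW_S = 6.0
DEFAULT_OVERLAP = 0.75

_TOL = 1e-9


class EmptyDatasetError(ValueError):
    """A window selection matched nothing (raised instead of training silently)."""


@dataclass(frozen=True)
class Window:
    """One classification unit: a 3xL acceleration matrix plus provenance."""

    a: np.ndarray  # (3, L), g
    activity: str
    subject_id: str
    group: str
    device: str
    session_id: str
    start_s: float
    sample_rate_hz: float

    @property
    def L(self) -> int:
        return self.a.shape[1]


def window_counts(duration_s: float, window_s: float, stride_s: float) -> int:
    """Closed-form number of full windows in an interval of ``duration_s``."""
    if duration_s < window_s - _TOL:
        return 0
    return int(np.floor((duration_s - window_s) / stride_s + _TOL)) + 1


def segment(
    recording: Recording,
    window_s: float = DEFAULT_WINDOW_S,
    overlap: float = DEFAULT_OVERLAP,
) -> list[Window]:
    """Cut one recording into single-activity windows.

    ``overlap`` is the fraction of shared samples between consecutive windows
    (0 <= overlap < 1). ``window_s * sample_rate`` must be a whole number of
    samples.
    """
    if not 0 <= overlap < 1:
        raise ValidationError(f"overlap must be in [0, 1), got {overlap}")
    rate = recording.sample_rate_hz
    L_f = window_s * rate
    L = int(round(L_f))
    if abs(L_f - L) > 1e-6 or L < 1:
        raise ValidationError(
            f"window of {window_s} s at {rate} Hz is {L_f} samples; must be integral"
        )
    stride = int(round(window_s * (1 - overlap) * rate))
    stride = max(stride, 1)
    t = recording.t
    windows: list[Window] = []
    for iv in recording.labels:
        i0 = int(np.searchsorted(t, iv.start_s - _TOL, side="left"))
        i1 = int(np.searchsorted(t, iv.end_s - _TOL, side="left"))  # half-open end
        start = i0
        while start + L <= i1:
            windows.append(
                Window(
                    a=recording.acc[start : start + L].T.copy(),
                    activity=iv.activity,
                    subject_id=recording.subject_id,
                    group=recording.group,
                    device=recording.device,
                    session_id=recording.session_id,
                    start_s=float(t[start]),
                    sample_rate_hz=rate,
                )
            )
            start += stride
    return windows


def window_dataset(
    cohort: Cohort,
    predicate: Callable[[Recording], bool] | None = None,
    window_s: float = DEFAULT_WINDOW_S,
    overlap: float = DEFAULT_OVERLAP,
) -> list[Window]:
    """All windows from selected recordings, in a stable order.

    Recordings are ordered by (subject, device, session) and windows by start
    time within each recording. Raises :class:`EmptyDatasetError` when the
    predicate selects nothing.
    """
    selected = cohort.select(predicate) if predicate else list(cohort)
    selected.sort(key=lambda r: r.key)
    windows: list[Window] = []
    for rec in selected:
        windows.extend(segment(rec, window_s=window_s, overlap=overlap))
    if not windows:
        raise EmptyDatasetError("selection produced no windows")
    return windows
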