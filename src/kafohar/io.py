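"""Reading and writing accelerometer recordings, label intervals, and cohorts.

A recording is one subject-session-device stream from a waist-worn triaxial
accelerometer (Actigraph-style CSV export: raw samples in g-units at a nominal
30 Hz), plus a sidecar file of labeled activity intervals. A cohort is a set
of recordings described by a JSON manifest.

Dialects
--------
* recording CSV: header ``timestamp_s,ax_g,ay_g,az_g``; 0-based seconds,
  accelerations in g; comma separator, decimal point, UTF-8.
* labels CSV: header ``start_s,end_s,activity``; half-open ``[start, end)``
  intervals in seconds.
* cohort manifest: JSON list of objects with keys ``file``, ``labels_file``,
  ``subject_id``, ``group``, ``device``, ``session_id`` (paths relative to the
  manifest).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

ACTIVITIES: tuple[str, ...] = ("sit", "stand", "walk", "stairs_up", "stairs_down")
GROUPS: tuple[str, ...] = ("healthy", "patient")
DEVICES: tuple[str, ...] = ("none", "control", "novel")

#: devices permitted per subject group: healthy subjects wear no orthosis,
#: patients are recorded with both their control KAFO and the novel KAFO
GROUP_DEVICES = {"healthy": ("none",), "patient": ("control", "novel")}

DEFAULT_SAMPLE_RATE_HZ = 30.0

_TIME_TOL_S = 1e-6


class ValidationError(ValueError):
    """An object violates a structural invariant (timestamps, labels, groups)."""


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending line."""


@dataclass(frozen=True)
class LabelInterval:
    """Half-open activity interval ``[start_s, end_s)`` in recording time."""

    start_s: float
    end_s: float
    activity: str

    def __post_init__(self) -> None:
        if self.activity not in ACTIVITIES:
            raise ValidationError(
                f"unknown activity {self.activity!r}; expected one of {ACTIVITIES}"
            )
        if not self.start_s < self.end_s:
            raise ValidationError(
                f"label interval must have start < end, got [{self.start_s}, {self.end_s})"
            )

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class Recording:
    """One accelerometer stream with its activity labels and provenance.

    ``t`` is seconds from recording start (0-based, uniformly spaced at
    ``1/sample_rate_hz``); ``acc`` is an (n, 3) array of x, y, z accelerations
    in g.
    """

    subject_id: str
    group: str
    device: str
    session_id: str
    t: np.ndarray
    acc: np.ndarray
    labels: list[LabelInterval] = field(default_factory=list)
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.acc = np.asarray(self.acc, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.group not in GROUPS:
            raise ValidationError(f"unknown group {self.group!r}")
        if self.device not in DEVICES:
            raise ValidationError(f"unknown device {self.device!r}")
        if self.device not in GROUP_DEVICES[self.group]:
            raise ValidationError(
                f"group {self.group!r} cannot wear device {self.device!r}"
            )
        if self.sample_rate_hz <= 0:
            raise ValidationError("sample_rate_hz must be positive")
        if self.t.ndim != 1 or self.acc.shape != (self.t.size, 3):
            raise ValidationError(
                f"samples must be (n,) times and (n, 3) accelerations, "
                f"got t{self.t.shape} acc{self.acc.shape}"
            )
        if self.t.size:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                i = int(np.argmax(dt <= 0))
                raise ValidationError(
                    f"timestamps not strictly increasing at sample {i + 1} "
                    f"(t={self.t[i + 1]:.6f} after t={self.t[i]:.6f})"
                )
            if np.any(np.abs(dt - 1.0 / self.sample_rate_hz) > _TIME_TOL_S):
                i = int(np.argmax(np.abs(dt - 1.0 / self.sample_rate_hz) > _TIME_TOL_S))
                raise ValidationError(
                    f"timestamp spacing at sample {i + 1} is {dt[i]:.6g} s, "
                    f"expected {1.0 / self.sample_rate_hz:.6g} s"
                )
        _check_intervals(self.labels)
        if self.labels:
            if not self.t.size:
                raise ValidationError("labeled recording has no samples")
            t0, t1 = self.t[0], self.t[-1]
            for iv in self.labels:
                # end may reach one sample period past the last sample: the
                # interval is half-open and the final sample lives at t1.
                if iv.start_s < t0 - _TIME_TOL_S or iv.end_s > t1 + 1.0 / self.sample_rate_hz + _TIME_TOL_S:
                    raise ValidationError(
                        f"label {iv.activity} [{iv.start_s}, {iv.end_s}) outside "
                        f"recorded range [{t0}, {t1}]"
                    )

    @property
    def n_samples(self) -> int:
        return int(self.t.size)

    @property
    def duration_s(self) -> float:
        return float(self.t[-1] - self.t[0]) if self.t.size else 0.0

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.subject_id, self.device, self.session_id)


def _check_intervals(labels: Sequence[LabelInterval]) -> None:
    ordered = sorted(labels, key=lambda iv: iv.start_s)
    for a, b in zip(ordered, ordered[1:]):
        if b.start_s < a.end_s - _TIME_TOL_S:
            raise ValidationError(
                f"overlapping label intervals: {a.activity} [{a.start_s}, {a.end_s}) "
                f"and {b.activity} [{b.start_s}, {b.end_s})"
            )


@dataclass
class Cohort:
    """A set of recordings with unique (subject, device, session) keys."""

    recordings: list[Recording]

    def __post_init__(self) -> None:
        keys = [r.key for r in self.recordings]
        if len(set(keys)) != len(keys):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise ValidationError(f"duplicate (subject, device, session) keys: {dupes}")

    def __len__(self) -> int:
        return len(self.recordings)

    def __iter__(self):
        return iter(self.recordings)

    def select(self, predicate: Callable[[Recording], bool]) -> list[Recording]:
        return [r for r in self.recordings if predicate(r)]

    def subjects(self, group: str | None = None) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.recordings:
            if group is None or r.group == group:
                seen.setdefault(r.subject_id, None)
        return list(seen)

    def index(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": [r.subject_id for r in self.recordings],
                "group": [r.group for r in self.recordings],
                "device": [r.device for r in self.recordings],
                "session_id": [r.session_id for r in self.recordings],
                "n_samples": [r.n_samples for r in self.recordings],
            }
        )

    def with_devices_swapped(self) -> "Cohort":
        """Relabel control<->novel on every patient recording (healthy untouched)."""
        swap = {"control": "novel", "novel": "control", "none": "none"}
        return Cohort([replace(r, device=swap[r.device]) for r in self.recordings])


# ---------------------------------------------------------------------------
# readers / writers


def read_recording_csv(
    path: str | Path,
    *,
    subject_id: str,
    group: str,
    device: str,
    session_id: str,
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ,
    labels: Sequence[LabelInterval] | None = None,
    column_map: dict[str, str] | None = None,
) -> Recording:
    """Read one recording CSV into a validated :class:`Recording`.

    ``column_map`` maps the canonical names (``timestamp_s``, ``ax_g``,
    ``ay_g``, ``az_g``) onto the file's header names, to absorb export-dialect
    variants; axis order x, y, z is taken from the mapping, not the file.
    """
    path = Path(path)
    colmap = {"timestamp_s": "timestamp_s", "ax_g": "ax_g", "ay_g": "ay_g", "az_g": "az_g"}
    if column_map:
        colmap.update(column_map)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # malformed CSV structure
        raise ParseError(f"{path}: {exc}") from exc
    missing = [v for v in colmap.values() if v not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}; found {list(df.columns)}")
    cols = [colmap["timestamp_s"], colmap["ax_g"], colmap["ay_g"], colmap["az_g"]]
    numeric = df[cols].apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().any(axis=1)
    if bad.any():
        row = int(np.argmax(bad.to_numpy()))
        raise ParseError(
            f"{path}: non-numeric value on data line {row + 2}"  # +1 header, +1 one-based
        )
    t = numeric[cols[0]].to_numpy(dtype=float)
    acc = numeric[cols[1:]].to_numpy(dtype=float)
    return Recording(
        subject_id=subject_id,
        group=group,
        device=device,
        session_id=session_id,
        t=t,
        acc=acc,
        labels=list(labels) if labels else [],
        sample_rate_hz=sample_rate_hz,
    )


def read_labels(path: str | Path) -> list[LabelInterval]:
    """Read a labels CSV into sorted, validated, non-overlapping intervals."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    for col in ("start_s", "end_s", "activity"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    intervals = [
        LabelInterval(float(row.start_s), float(row.end_s), str(row.activity))
        for row in df.itertuples()
    ]
    intervals.sort(key=lambda iv: iv.start_s)
    _check_intervals(intervals)
    return intervals


def write_labels(labels: Iterable[LabelInterval], path: str | Path) -> None:
    df = pd.DataFrame(
        [{"start_s": iv.start_s, "end_s": iv.end_s, "activity": iv.activity} for iv in labels]
    )
    df.to_csv(path, index=False, float_format="%.9f")


def write_recording_csv(recording: Recording, path: str | Path) -> None:
    """Write the sample stream; labels go to a sidecar via :func:`write_labels`.

    Refuses empty recordings. Round-trip through :func:`read_recording_csv`
    reproduces timestamps and accelerations to 1e-9.
    """
    if recording.n_samples == 0:
        raise ValidationError("refusing to write a recording with no samples")
    df = pd.DataFrame(
        {
            "timestamp_s": recording.t,
            "ax_g": recording.acc[:, 0],
            "ay_g": recording.acc[:, 1],
            "az_g": recording.acc[:, 2],
        }
    )
    df.to_csv(path, index=False, float_format="%.10g")


def write_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    """Write every recording + labels and a manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for rec in cohort:
        stem = f"{rec.subject_id}_{rec.device}_{rec.session_id}"
        write_recording_csv(rec, out_dir / f"{stem}.csv")
        write_labels(rec.labels, out_dir / f"{stem}_labels.csv")
        entries.append(
            {
                "file": f"{stem}.csv",
                "labels_file": f"{stem}_labels.csv",
                "subject_id": rec.subject_id,
                "group": rec.group,
                "device": rec.device,
                "session_id": rec.session_id,
                "sample_rate_hz": rec.sample_rate_hz,
            }
        )
    manifest = out_dir / "manifest.json"
    manifest.write_text(json.dumps(entries, indent=1, sort_keys=True))
    return manifest


def read_cohort(manifest_path: str | Path) -> Cohort:
    """Assemble a cohort from a manifest written by :func:`write_cohort`."""
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    entries = json.loads(manifest_path.read_text())
    recordings = []
    for e in entries:
        labels = read_labels(base / e["labels_file"]) if e.get("labels_file") else []
        recordings.append(
            read_recording_csv(
                base / e["file"],
                subject_id=e["subject_id"],
                group=e["group"],
                device=e["device"],
                session_id=e["session_id"],
                sample_rate_hz=float(e.get("sample_rate_hz", DEFAULT_SAMPLE_RATE_HZ)),
                labels=labels,
            )
        )
    return Cohort(recordings)
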