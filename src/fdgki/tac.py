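"""Framed time-activity curves (TACs) and their CSV dialect.

A dynamic PET recording is reconstructed in frames. Region-mean or
blood-pool concentrations per frame form a time-activity curve: the
universal I/O object of this package. Times are minutes post-injection;
concentrations are decay-corrected and carried in whatever internally
consistent unit the scanner produced (the unit string is opaque metadata,
never converted).

All protocols handled here are harmonized to 67 min of recording: a frame
extending past 67 min is truncated by clipping its end time, keeping the
reconstructed value as-is.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

#: End of the harmonized recording, minutes post-injection.
TRUNCATION_MIN = 67.0

_OVERLAP_TOL = 1e-9

TAC_COLUMNS = ("frame_start_min", "frame_end_min", "value")

MANIFEST_COLUMNS = (
    "subject_id",
    "age_years",
    "site",
    "idif_path",
    "gm_path",
    "wm_path",
)


@dataclass(frozen=True)
class FrameSchedule:
    """Frame timing of a dynamic PET recording.

    Parameters
    ----------
    start, end
        Frame start/end times, minutes post-injection. Frames must be
        strictly increasing, non-overlapping, and end at or before
        ``TRUNCATION_MIN``.
    """

    start: np.ndarray
    end: np.ndarray

    def __post_init__(self) -> None:
        start = np.asarray(self.start, dtype=float)
        end = np.asarray(self.end, dtype=float)
        object.__setattr__(self, "start", start)
        object.__setattr__(self, "end", end)
        if start.ndim != 1 or start.shape != end.shape:
            raise ValidationError("start and end must be 1-D arrays of equal length")
        if start.size == 0:
            raise ValidationError("empty frame schedule")
        if not np.all(np.isfinite(start)) or not np.all(np.isfinite(end)):
            raise ValidationError("non-finite frame times")
        if np.any(start < 0):
            raise ValidationError("negative frame start time")
        if not np.all(np.diff(start) > 0):
            raise ValidationError("frame_start must be strictly increasing")
        if not np.all(end > start):
            raise ValidationError("frame_end must exceed frame_start for every frame")
        if np.any(end[:-1] > start[1:] + _OVERLAP_TOL):
            raise ValidationError("overlapping frames")
        if end[-1] > TRUNCATION_MIN + _OVERLAP_TOL:
            raise ValidationError(
                f"schedule extends past the {TRUNCATION_MIN:.0f}-min truncation; "
                "clip the final frame first"
            )

    @property
    def mid(self) -> np.ndarray:
        """Arithmetic frame midpoints (minutes)."""
        return 0.5 * (self.start + self.end)

    @property
    def duration(self) -> np.ndarray:
        """Frame durations (minutes)."""
        return self.end - self.start

    def __len__(self) -> int:
        return int(self.start.size)

    def window_mask(self, t_lo: float, t_hi: float) -> np.ndarray:
        """Boolean mask of frames whose mid-time lies in the closed window."""
        mid = self.mid
        return (mid >= t_lo) & (mid <= t_hi)

    def approx_equal(self, other: "FrameSchedule", tol: float = 1e-9) -> bool:
        return (
            len(self) == len(other)
            and np.allclose(self.start, other.start, atol=tol)
            and np.allclose(self.end, other.end, atol=tol)
        )


@dataclass(frozen=True)
class TimeActivityCurve:
    """Decay-corrected concentration per frame for one region or blood pool."""

    schedule: FrameSchedule
    value: np.ndarray
    label: str = "other"
    subject_id: str = ""
    units: str = "arbitrary"

    def __post_init__(self) -> None:
        value = np.asarray(self.value, dtype=float)
        object.__setattr__(self, "value", value)
        if value.ndim != 1 or value.size != len(self.schedule):
            raise ValidationError("value length must equal frame count")
        if not np.all(np.isfinite(value)):
            raise ValidationError("non-finite concentration value")
        bad = np.flatnonzero(value < 0)
        if bad.size:
            raise ValidationError(f"negative concentration at row {bad[0]}")

    @property
    def mid(self) -> np.ndarray:
        return self.schedule.mid

    def __len__(self) -> int:
        return len(self.schedule)

    def window(self, t_lo: float, t_hi: float) -> "TimeActivityCurve":
        """Restrict to frames with mid-time in the closed window [t_lo, t_hi]."""
        m = self.schedule.window_mask(t_lo, t_hi)
        return replace(
            self,
            schedule=FrameSchedule(self.schedule.start[m], self.schedule.end[m]),
            value=self.value[m],
        )

    def scaled(self, factor: float) -> "TimeActivityCurve":
        return replace(self, value=self.value * factor)


@dataclass
class SubjectRecord:
    """One subject: metadata plus blood (IDIF), gray- and white-matter TACs."""

    subject_id: str
    age: float
    site: str
    idif: TimeActivityCurve
    gm: TimeActivityCurve
    wm: TimeActivityCurve
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.age > 0:
            raise ValidationError(f"subject {self.subject_id}: age must be positive")
        for tac in (self.gm, self.wm):
            if not tac.schedule.approx_equal(self.idif.schedule):
                raise ValidationError(
                    f"subject {self.subject_id}: all TACs must share one frame schedule"
                )


def _truncate_frames(df: pd.DataFrame) -> pd.DataFrame:
    """Clip frame ends past the harmonized 67-min truncation; values kept as-is."""
    df = df[df["frame_start_min"] < TRUNCATION_MIN].copy()
    df.loc[df["frame_end_min"] > TRUNCATION_MIN, "frame_end_min"] = TRUNCATION_MIN
    return df


def read_tac(path, label: str | None = None) -> TimeActivityCurve:
    """Read a TAC from CSV.

    The dialect is comma-separated with a mandatory header
    ``frame_start_min,frame_end_min,value``; lines beginning with ``#`` may
    carry ``key: value`` metadata (subject_id, label, units). A final frame
    extending past 67 min is clipped to 67 min with its value unchanged.
    """
    meta: dict[str, str] = {}
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    body_lines = []
    for line in text.splitlines():
        if line.startswith("#"):
            stripped = line.lstrip("#").strip()
            if ":" in stripped:
                key, _, val = stripped.partition(":")
                meta[key.strip()] = val.strip()
        else:
            body_lines.append(line)
    try:
        df = pd.read_csv(io.StringIO("\n".join(body_lines)))
    except Exception as exc:  # noqa: BLE001 - wrap any parse failure
        raise FormatError(f"{path}: cannot parse CSV ({exc})") from exc
    missing = [c for c in TAC_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    if len(df) < 3:
        raise FormatError(f"{path}: a TAC needs at least 3 frames")
    df = _truncate_frames(df[list(TAC_COLUMNS)].astype(float))
    schedule = FrameSchedule(df["frame_start_min"].to_numpy(), df["frame_end_min"].to_numpy())
    return TimeActivityCurve(
        schedule=schedule,
        value=df["value"].to_numpy(),
        label=label or meta.get("label", "other"),
        subject_id=meta.get("subject_id", ""),
        units=meta.get("units", "arbitrary"),
    )


def write_tac(tac: TimeActivityCurve, path) -> None:
    """Write a TAC as CSV at full float precision (round-trips via read_tac)."""
    with open(path, "w", encoding="utf-8") as fh:
        if tac.subject_id:
            fh.write(f"# subject_id: {tac.subject_id}\n")
        fh.write(f"# label: {tac.label}\n")
        fh.write(f"# units: {tac.units}\n")
        fh.write(",".join(TAC_COLUMNS) + "\n")
        for s, e, v in zip(tac.schedule.start, tac.schedule.end, tac.value):
            fh.write(f"{s:.17g},{e:.17g},{v:.17g}\n")


def read_manifest(path) -> list[SubjectRecord]:
    """Read a subject manifest CSV and load every referenced TAC.

    Relative TAC paths are resolved against the manifest's directory.
    """
    import os

    df = pd.read_csv(path, comment="#")
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: manifest missing columns {missing}")
    base = os.path.dirname(os.fspath(path))

    def resolve(p: str) -> str:
        return p if os.path.isabs(p) else os.path.join(base, p)

    subjects = []
    for row in df.itertuples(index=False):
        subjects.append(
            SubjectRecord(
                subject_id=str(row.subject_id),
                age=float(row.age_years),
                site=str(row.site),
                idif=read_tac(resolve(row.idif_path), label="blood"),
                gm=read_tac(resolve(row.gm_path), label="GM"),
                wm=read_tac(resolve(row.wm_path), label="WM"),
            )
        )
    return subjects


def write_manifest(subjects: list[SubjectRecord], out_dir, manifest_name="manifest.csv") -> str:
    """Write per-subject TAC CSVs plus a manifest referencing them."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for s in subjects:
        paths = {}
        for key, tac in (("idif", s.idif), ("gm", s.gm), ("wm", s.wm)):
            fname = f"{s.subject_id}_{key}.csv"
            write_tac(tac, os.path.join(out_dir, fname))
            paths[key] = fname
        rows.append(
            {
                "subject_id": s.subject_id,
                "age_years": s.age,
                "site": s.site,
                "idif_path": paths["idif"],
                "gm_path": paths["gm"],
                "wm_path": paths["wm"],
            }
        )
    manifest_path = os.path.join(out_dir, manifest_name)
    pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS)).to_csv(manifest_path, index=False)
    return manifest_path
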