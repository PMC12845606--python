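"""Reading and writing of on-disk pipeline artifacts.

Signals travel as delimited text matrices (one header row of muscle labels,
one row per sample, comma or tab, auto-detected) with a JSON metadata
sidecar; cycle/phase events as tidy CSV; synergy sets and reference sets as
JSON documents with explicit shape fields; feature tables as tidy CSV.
Everything is validated on ingestion -- channels are never silently
reordered and read/write round-trips at full float precision.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PHASES",
    "PHASE_ALIASES",
    "GROUPS",
    "SESSIONS",
    "TrialMeta",
    "EmgRecording",
    "CycleEvents",
    "PipelineConfig",
    "IngestionError",
    "read_recording",
    "write_recording",
    "read_events",
    "write_events",
    "read_feature_table",
    "write_feature_table",
]

#: Canonical names of the four consecutive phases of one breaststroke-kick
#: cycle, in temporal order.
PHASES: tuple[str, ...] = ("leg-retraction", "leg-flipping", "pedal-clamp", "glide")

#: Synonyms seen in the literature, normalized at ingestion.
PHASE_ALIASES: dict[str, str] = {
    "leg recovery": "leg-retraction",
    "leg-recovery": "leg-retraction",
    "leg retraction": "leg-retraction",
    "foot rotation": "leg-flipping",
    "foot-rotation": "leg-flipping",
    "leg rotation": "leg-flipping",
    "leg-rotation": "leg-flipping",
    "leg flipping": "leg-flipping",
    "kick-squeeze": "pedal-clamp",
    "kick squeeze": "pedal-clamp",
    "kick-and-squeeze": "pedal-clamp",
    "pedal clamp": "pedal-clamp",
    "gliding": "glide",
}

GROUPS: tuple[str, str] = ("experimental", "control")
SESSIONS: tuple[str, str] = ("pre", "post")


class IngestionError(ValueError):
    """Raised when an on-disk artifact fails validation."""


def canonical_phase(name: str) -> str:
    """Map a phase name or known synonym to its canonical form."""
    key = name.strip().lower()
    if key in PHASES:
        return key
    if key in PHASE_ALIASES:
        return PHASE_ALIASES[key]
    raise IngestionError(
        f"unknown phase name {name!r}; expected one of {list(PHASES)} "
        f"(or a known synonym)"
    )


@dataclass(frozen=True)
class TrialMeta:
    """Identity of one recorded trial."""

    subject: str
    group: str
    session: str
    trial: str = "t1"

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise IngestionError(f"unknown group {self.group!r}; expected {GROUPS}")
        if self.session not in SESSIONS:
            raise IngestionError(
                f"unknown session {self.session!r}; expected {SESSIONS}"
            )


@dataclass
class EmgRecording:
    """Multi-channel surface-EMG recording.

    Parameters
    ----------
    muscle_labels
        Channel names, in acquisition order (length ``m``).
    fs
        Sampling rate in Hz.
    signal
        ``m x T`` array of amplitudes in microvolts.  Sample ``i`` covers the
        half-open interval ``[i/fs, (i+1)/fs)`` seconds from trial start.
    meta
        Trial identity (subject, group, session, trial).
    """

    muscle_labels: list[str]
    fs: float
    signal: np.ndarray
    meta: TrialMeta

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.fs <= 0:
            raise IngestionError(f"sampling rate must be positive, got {self.fs}")
        if self.signal.ndim != 2:
            raise IngestionError("signal must be a 2-D (channels x samples) array")
        m = len(self.muscle_labels)
        if m < 2:
            raise IngestionError(f"need at least 2 channels, got {m}")
        if self.signal.shape[0] != m:
            raise IngestionError(
                f"{m} muscle labels but {self.signal.shape[0]} signal rows"
            )
        if not np.all(np.isfinite(self.signal)):
            bad = np.argwhere(~np.isfinite(self.signal))[0]
            raise IngestionError(
                f"non-finite value at channel {self.muscle_labels[bad[0]]!r}, "
                f"sample {bad[1]}"
            )

    @property
    def n_channels(self) -> int:
        return len(self.muscle_labels)

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def replace_signal(self, signal: np.ndarray) -> "EmgRecording":
        """Same channels/metadata with a new signal array."""
        return EmgRecording(list(self.muscle_labels), self.fs, signal, self.meta)


@dataclass
class CycleEvents:
    """Phase boundaries for each stroke cycle.

    ``table`` has one row per (cycle, phase): columns ``cycle`` (int),
    ``phase`` (canonical name), ``start_s``, ``end_s``.  Within a cycle the
    four phases are contiguous, non-overlapping, and in canonical order;
    intervals are half-open ``[start_s, end_s)``.
    """

    table: pd.DataFrame

    _TOL = 1e-9

    def __post_init__(self) -> None:
        df = self.table.copy()
        required = {"cycle", "phase", "start_s", "end_s"}
        if not required.issubset(df.columns):
            raise IngestionError(f"events table needs columns {sorted(required)}")
        df["phase"] = df["phase"].map(canonical_phase)
        for cyc, grp in df.groupby("cycle"):
            grp = grp.reset_index(drop=True)
            if list(grp["phase"]) != list(PHASES):
                raise IngestionError(
                    f"cycle {cyc}: phases must appear exactly once each, in order "
                    f"{list(PHASES)}; got {list(grp['phase'])}"
                )
            if not (grp["end_s"] > grp["start_s"]).all():
                raise IngestionError(f"cycle {cyc}: each phase needs end_s > start_s")
            starts = grp["start_s"].to_numpy()
            ends = grp["end_s"].to_numpy()
            if np.any(np.abs(starts[1:] - ends[:-1]) > self._TOL):
                raise IngestionError(
                    f"cycle {cyc}: phases must be contiguous and non-overlapping "
                    f"(half-open [start, end) intervals)"
                )
        self.table = df.reset_index(drop=True)

    @property
    def cycle_ids(self) -> list[int]:
        return sorted(self.table["cycle"].unique().tolist())

    @property
    def n_cycles(self) -> int:
        return self.table["cycle"].nunique()

    def cycle(self, cycle_id: int) -> pd.DataFrame:
        """The four phase rows of one cycle, in canonical order."""
        out = self.table[self.table["cycle"] == cycle_id].reset_index(drop=True)
        if out.empty:
            raise KeyError(f"no cycle {cycle_id} in events")
        return out

    def cycle_span(self, cycle_id: int) -> tuple[float, float]:
        rows = self.cycle(cycle_id)
        return float(rows["start_s"].iloc[0]), float(rows["end_s"].iloc[-1])


# ---------------------------------------------------------------------------
# pipeline configuration


@dataclass
class PipelineConfig:
    """All tunable knobs of the pipeline with their defaults.

    Thresholds mirror the published procedure: VAF > 0.9 for model order,
    weight >= 0.3 for major contributors, Pearson r > 0.6 for matching.
    """

    # preprocessing
    bandpass_low_hz: float = 10.0
    bandpass_high_hz: float = 400.0
    bandpass_order: int = 4
    envelope_cutoff_hz: float = 10.0
    envelope_order: int = 4
    points_per_phase: int = 101
    cycle_select: str = "middle3"

    # NMF / model order
    k_min: int = 1
    k_max: int = 8
    nmf_restarts: int = 20
    nmf_tol: float = 1e-6
    nmf_max_iter: int = 500
    nmf_seed: int = 0
    vaf_threshold: float = 0.9
    vaf_centered_sst: bool = True
    contributor_threshold: float = 0.3

    # clustering / matching
    cluster_restarts: int = 50
    cluster_seed: int = 0
    cluster_s_min: int = 1
    cluster_s_max: int = 8
    cluster_drop_tol: float = 0.10
    pooled_reference: bool = False
    match_r_threshold: float = 0.6
    match_method: str = "greedy"  # or "hungarian"
    activation_threshold: float = 0.2

    # statistics
    alpha: float = 0.05
    simple_effect_family: int = 4
    outlier_mode: str = "report"  # "report" | "remove"

    def __post_init__(self) -> None:
        if not 0 < self.vaf_threshold < 1:
            raise ValueError("vaf_threshold must lie in (0, 1)")
        if not 0 < self.match_r_threshold < 1:
            raise ValueError("match_r_threshold must lie in (0, 1)")
        if self.points_per_phase < 2:
            raise ValueError("points_per_phase must be >= 2")
        if not 0 < self.activation_threshold < 1:
            raise ValueError("activation_threshold must lie in (0, 1)")
        if self.cycle_select not in ("middle3", "all"):
            raise ValueError("cycle_select must be 'middle3' or 'all'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise IngestionError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# readers / writers


def _read_delimited(path: str | Path) -> pd.DataFrame:
    """Read a comma- or tab-delimited table, auto-detecting the separator."""
    with open(path) as fh:
        first = fh.readline()
    sep = "\t" if first.count("\t") >= first.count(",") and "\t" in first else ","
    return pd.read_csv(path, sep=sep)


def read_recording(signal_path: str | Path, meta_path: str | Path) -> EmgRecording:
    """Load a recording from a delimited signal matrix plus JSON metadata.

    The signal file has one header row of muscle labels and one row per
    sample; label order is preserved.  Metadata supplies ``fs_hz``,
    ``subject``, ``group``, ``session`` and optionally ``trial``.
    """
    df = _read_delimited(signal_path)
    if df.shape[1] < 2:
        raise IngestionError(
            f"{signal_path}: need at least 2 channels, found {df.shape[1]}"
        )
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = int(vals.isna().idxmax())
            raise IngestionError(
                f"{signal_path}: non-numeric or blank cell at row {row}, "
                f"column {col!r}"
            )
    with open(meta_path) as fh:
        meta = json.load(fh)
    fs = float(meta.get("fs_hz", 0))
    if fs <= 0:
        raise IngestionError(f"{meta_path}: fs_hz must be positive, got {fs}")
    trial = TrialMeta(
        subject=str(meta["subject"]),
        group=str(meta["group"]),
        session=str(meta["session"]),
        trial=str(meta.get("trial", "t1")),
    )
    return EmgRecording(
        muscle_labels=[str(c) for c in df.columns],
        fs=fs,
        signal=df.to_numpy(dtype=float).T,
        meta=trial,
    )


def write_recording(
    rec: EmgRecording, signal_path: str | Path, meta_path: str | Path
) -> None:
    """Write a recording as CSV matrix + JSON metadata (read_recording inverse)."""
    df = pd.DataFrame(rec.signal.T, columns=rec.muscle_labels)
    df.to_csv(signal_path, index=False)
    meta = {
        "subject": rec.meta.subject,
        "group": rec.meta.group,
        "session": rec.meta.session,
        "trial": rec.meta.trial,
        "fs_hz": rec.fs,
    }
    with open(meta_path, "w") as fh:
        json.dump(meta, fh, indent=1)


def read_events(path: str | Path) -> CycleEvents:
    """Load and validate a cycle/phase event table."""
    df = _read_delimited(path)
    return CycleEvents(df)


def write_events(events: CycleEvents, path: str | Path) -> None:
    events.table.to_csv(path, index=False)


def write_feature_table(rows: pd.DataFrame | Sequence[dict], path: str | Path) -> None:
    """Write a tidy feature table (one value per row) as CSV.

    Values round-trip at full double precision (pandas writes ``repr``
    floats).  An empty row collection yields a header-only file.
    """
    if not isinstance(rows, pd.DataFrame):
        rows = pd.DataFrame(
            list(rows),
            columns=["subject", "group", "session", "measure", "value"]
            if len(rows) == 0
            else None,
        )
    rows.to_csv(path, index=False)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    # round_trip parser: values written by write_feature_table come back
    # bit-identical
    return pd.read_csv(path, float_precision="round_trip")


# --- JSON documents for synergy artifacts ----------------------------------


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_json_document(doc: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(_jsonable(doc), fh, indent=1)


def read_json_document(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
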