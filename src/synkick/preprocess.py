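"""Raw EMG to normalized phase-segmented activation envelopes and
time-domain features.

The envelope chain follows the standard surface-EMG recipe: 10-400 Hz
Butterworth bandpass, mean removal, full-wave rectification, 4th-order
zero-phase 10 Hz low-pass (linear envelope), per-channel peak-amplitude
normalization, then time-normalization of each of the four kick phases to
101 points and ensemble-averaging of the middle three cycles.  All filters
run forward-backward (``sosfiltfilt``), so net phase shift is zero and the
effective order doubles; reflective padding suppresses startup transients.

Time-domain features (iEMG in uV*s, RMS in uV) are computed per muscle and
phase on the rectified, filtered signal *before* amplitude normalization
and resampling, on the original samples -- normalization would destroy the
physical units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .emg_io import PHASES, CycleEvents, EmgRecording, PipelineConfig

__all__ = [
    "EnvelopeMatrix",
    "bandpass",
    "demean",
    "rectify",
    "envelope",
    "peak_normalize",
    "segment_and_time_normalize",
    "select_cycles",
    "ensemble_average",
    "compute_iemg",
    "compute_rms",
    "extract_envelope_matrix",
    "time_domain_features",
]


@dataclass
class EnvelopeMatrix:
    """Normalized, phase-segmented, time-normalized activation envelopes.

    ``values`` is ``m x n`` with ``n = 4 * points_per_phase`` columns per
    ensemble-averaged cycle; ``phase_boundaries`` are the column indices
    where each phase block starts; ``cycle_fraction_map`` gives each
    column's position as a fraction of the real cycle in [0, 1].
    """

    muscle_labels: list[str]
    values: np.ndarray
    phase_boundaries: list[int]
    cycle_fraction_map: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.cycle_fraction_map = np.asarray(self.cycle_fraction_map, dtype=float)
        if self.values.shape != (len(self.muscle_labels), self.cycle_fraction_map.size):
            raise ValueError("values shape must be (labels, fraction-map length)")
        if np.any(self.values < 0):
            raise ValueError("envelope values must be non-negative")
        if np.any(np.diff(self.cycle_fraction_map) < -1e-12):
            raise ValueError("cycle_fraction_map must be non-decreasing")

    @property
    def n_channels(self) -> int:
        return len(self.muscle_labels)


def _sosfiltfilt(sos: np.ndarray, x: np.ndarray) -> np.ndarray:
    # generous reflective padding so short segments keep clean edges
    padlen = min(x.shape[-1] - 1, 3 * 2 * sos.shape[0] * 10)
    return sps.sosfiltfilt(sos, x, axis=-1, padlen=padlen)


def bandpass(
    rec: EmgRecording, low: float = 10.0, high: float = 400.0, order: int = 4
) -> EmgRecording:
    """Zero-phase Butterworth bandpass (default 10-400 Hz)."""
    if rec.fs <= 2 * high:
        raise ValueError(
            f"sampling rate {rec.fs} Hz too low for a {high} Hz band edge"
        )
    sos = sps.butter(order, (low, high), btype="bandpass", fs=rec.fs, output="sos")
    return rec.replace_signal(_sosfiltfilt(sos, rec.signal))


def demean(rec: EmgRecording) -> EmgRecording:
    """Remove each channel's mean (DC offset)."""
    return rec.replace_signal(rec.signal - rec.signal.mean(axis=1, keepdims=True))


def rectify(rec: EmgRecording) -> EmgRecording:
    """Full-wave rectification (elementwise absolute value)."""
    return rec.replace_signal(np.abs(rec.signal))


def envelope(rec: EmgRecording, cutoff: float = 10.0, order: int = 4) -> EmgRecording:
    """Linear envelope: zero-phase Butterworth low-pass on rectified EMG.

    Numerical undershoot below zero is clipped.
    """
    sos = sps.butter(order, cutoff, btype="lowpass", fs=rec.fs, output="sos")
    out = _sosfiltfilt(sos, rec.signal)
    return rec.replace_signal(np.clip(out, 0.0, None))


def peak_normalize(rec: EmgRecording) -> EmgRecording:
    """Divide each channel by its own maximum over the trial.

    Removes inter-muscle differences in absolute activation level; after
    this every channel peaks at exactly 1.
    """
    peaks = rec.signal.max(axis=1)
    bad = np.flatnonzero(peaks <= 0)
    if bad.size:
        raise ValueError(
            f"cannot peak-normalize all-zero channel(s): "
            f"{[rec.muscle_labels[i] for i in bad]}"
        )
    return rec.replace_signal(rec.signal / peaks[:, None])


def segment_and_time_normalize(
    rec: EmgRecording, events: CycleEvents, points_per_phase: int = 101
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Resample each phase of each cycle to a fixed number of points.

    For every cycle, each of the four phases is linearly interpolated onto
    ``points_per_phase`` points spanning the phase (fractions 0..1 of the
    half-open phase interval), then concatenated in canonical order.
    Returns per-cycle ``(matrix, cycle_fraction_map)`` pairs, where the
    fraction map locates each column in real-cycle time so phases of
    unequal duration are not distorted.
    """
    if points_per_phase < 2:
        raise ValueError("points_per_phase must be >= 2")
    t_samples = np.arange(rec.n_samples) / rec.fs
    out = []
    for cyc in events.cycle_ids:
        rows = events.cycle(cyc)
        cyc_start = rows["start_s"].iloc[0]
        cyc_dur = rows["end_s"].iloc[-1] - cyc_start
        blocks, fracs = [], []
        for _, ph in rows.iterrows():
            dur = ph["end_s"] - ph["start_s"]
            if dur * rec.fs < 2:
                raise ValueError(
                    f"cycle {cyc} phase {ph['phase']!r} shorter than 2 samples"
                )
            if ph["end_s"] > rec.duration_s + 0.5 / rec.fs:
                raise ValueError(
                    f"cycle {cyc} phase {ph['phase']!r} extends past the recording"
                )
            tq = ph["start_s"] + dur * np.linspace(0.0, 1.0, points_per_phase)
            # interpolate on sample times; clip query to the sampled range
            tq = np.clip(tq, t_samples[0], t_samples[-1])
            block = np.vstack(
                [np.interp(tq, t_samples, ch) for ch in rec.signal]
            )
            blocks.append(block)
            frac0 = (ph["start_s"] - cyc_start) / cyc_dur
            fracs.append(frac0 + (dur / cyc_dur) * np.linspace(0.0, 1.0, points_per_phase))
        out.append((np.hstack(blocks), np.concatenate(fracs)))
    return out


def select_cycles(n: int, select: str = "middle3") -> list[int]:
    """Indices of the cycles entering the ensemble average.

    ``middle3`` keeps the middle three cycles when at least three are
    available (e.g. cycles 2-4 of 5), all of them otherwise.
    """
    if select == "all" or n < 3:
        return list(range(n))
    if select != "middle3":
        raise ValueError(f"unknown cycle selection {select!r}")
    start = (n - 3) // 2
    return [start, start + 1, start + 2]


def ensemble_average(
    cycles: list[tuple[np.ndarray, np.ndarray]],
    muscle_labels: list[str],
    points_per_phase: int = 101,
    select: str = "middle3",
) -> EnvelopeMatrix:
    """Pointwise mean of the selected time-normalized cycles."""
    if not cycles:
        raise ValueError("need at least one cycle")
    shapes = {mat.shape for mat, _ in cycles}
    if len(shapes) != 1:
        raise ValueError(f"cycle matrices differ in shape: {shapes}")
    idx = select_cycles(len(cycles), select)
    mats = np.stack([cycles[i][0] for i in idx])
    frs = np.stack([cycles[i][1] for i in idx])
    boundaries = [p * points_per_phase for p in range(len(PHASES))]
    return EnvelopeMatrix(
        muscle_labels=list(muscle_labels),
        values=mats.mean(axis=0),
        phase_boundaries=boundaries,
        cycle_fraction_map=frs.mean(axis=0),
    )


def compute_iemg(segment: np.ndarray, fs: float) -> float:
    """Integrated EMG of one segment: sum of |x_n| scaled by the sample
    interval, so a signal in uV yields uV*s."""
    segment = np.asarray(segment, dtype=float)
    if segment.size == 0:
        raise ValueError("empty segment")
    return float(np.sum(np.abs(segment)) / fs)


def compute_rms(segment: np.ndarray) -> float:
    """Root-mean-square amplitude (uV in, uV out)."""
    segment = np.asarray(segment, dtype=float)
    if segment.size == 0:
        raise ValueError("empty segment")
    return float(np.sqrt(np.mean(segment**2)))


# ---------------------------------------------------------------------------
# full-chain conveniences


def _filtered_rectified(rec: EmgRecording, cfg: PipelineConfig) -> EmgRecording:
    out = bandpass(rec, cfg.bandpass_low_hz, cfg.bandpass_high_hz, cfg.bandpass_order)
    out = demean(out)
    return rectify(out)


def extract_envelope_matrix(
    rec: EmgRecording, events: CycleEvents, cfg: PipelineConfig | None = None
) -> EnvelopeMatrix:
    """Run the full preprocessing chain on one recording."""
    cfg = cfg or PipelineConfig()
    out = _filtered_rectified(rec, cfg)
    out = envelope(out, cfg.envelope_cutoff_hz, cfg.envelope_order)
    out = peak_normalize(out)
    cycles = segment_and_time_normalize(out, events, cfg.points_per_phase)
    return ensemble_average(
        cycles, rec.muscle_labels, cfg.points_per_phase, cfg.cycle_select
    )


def time_domain_features(
    rec: EmgRecording, events: CycleEvents, cfg: PipelineConfig | None = None
) -> pd.DataFrame:
    """iEMG (uV*s) and RMS (uV) per muscle and phase.

    Computed on the rectified, band-passed signal at original sampling,
    averaged over the same cycles that enter the ensemble average.
    """
    cfg = cfg or PipelineConfig()
    filt = _filtered_rectified(rec, cfg)
    idx = select_cycles(events.n_cycles, cfg.cycle_select)
    cycle_ids = [events.cycle_ids[i] for i in idx]
    rows = []
    for mi, muscle in enumerate(rec.muscle_labels):
        for phase in PHASES:
            iemgs, rmss = [], []
            for cyc in cycle_ids:
                ph = events.cycle(cyc)
                ph = ph[ph["phase"] == phase].iloc[0]
                lo = int(np.ceil(ph["start_s"] * rec.fs - 1e-9))
                hi = int(np.ceil(ph["end_s"] * rec.fs - 1e-9))
                seg = filt.signal[mi, lo:hi]
                iemgs.append(compute_iemg(seg, rec.fs))
                rmss.append(compute_rms(seg))
            rows.append(
                {
                    "subject": rec.meta.subject,
                    "group": rec.meta.group,
                    "session": rec.meta.session,
                    "muscle": muscle,
                    "phase": phase,
                    "iemg_uvs": float(np.mean(iemgs)),
                    "rms_uv": float(np.mean(rmss)),
                }
            )
    return pd.DataFrame(rows)
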