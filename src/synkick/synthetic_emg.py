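"""Synthetic surface-EMG cohorts with known ground-truth synergy structure.

The generator runs the synergy model forward: activation envelopes are built
as ``W x H`` from a ground-truth spatial weight matrix and per-synergy
activation bumps on the cycle-fraction axis, then turned into raw-looking
EMG by modulating a band-limited (20-400 Hz) unit-variance Gaussian carrier
and adding broadband noise.  Defaults encode the control-group
pre-intervention synergy structure reported for the breaststroke kick:
four synergies over ten lower-limb/trunk muscles, with activation bumps
whose peak times and 20%-of-peak spans match the published timing features.

Group x time effects are injected on ground-truth parameters (weights,
timing, per-phase channel gain), never on the signal, so downstream
statistical power is interpretable against known truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterator, Literal

import numpy as np
import pandas as pd
from scipy import signal as sps

from .emg_io import (
    GROUPS,
    PHASES,
    SESSIONS,
    CycleEvents,
    EmgRecording,
    TrialMeta,
)

__all__ = [
    "MUSCLES",
    "SYNERGY_NAMES",
    "Bump",
    "GroundTruth",
    "EffectInjection",
    "CohortSpec",
    "default_ground_truth",
    "make_envelope",
    "synthesize_recording",
    "synthesize_cohort",
    "sample_measure_table",
]

#: The ten recorded muscles, in acquisition order.
MUSCLES: tuple[str, ...] = (
    "tibialis-anterior",
    "gastrocnemius-medialis",
    "gastrocnemius-lateralis",
    "adductor-longus",
    "adductor-magnus",
    "biceps-femoris",
    "gluteus-maximus",
    "rectus-abdominis",
    "latissimus-dorsi",
    "trapezius",
)

SYNERGY_NAMES: tuple[str, ...] = ("SYN1", "SYN2", "SYN3", "SYN4")

# Control-group pre-intervention mean synergy weights, one column per synergy
# (rows ordered as MUSCLES).
_W_CONTROL_PRE = np.array(
    [
        # SYN1  SYN2  SYN3  SYN4
        [0.04, 0.93, 0.09, 0.02],  # tibialis anterior
        [0.84, 0.16, 0.21, 0.52],  # gastrocnemius medialis
        [0.86, 0.25, 0.14, 0.57],  # gastrocnemius lateralis
        [0.35, 0.29, 0.18, 0.76],  # adductor longus
        [0.40, 0.30, 0.26, 0.78],  # adductor magnus
        [0.11, 0.50, 0.12, 0.23],  # biceps femoris
        [0.49, 0.22, 0.14, 0.30],  # gluteus maximus
        [0.33, 0.29, 0.76, 0.12],  # rectus abdominis
        [0.16, 0.17, 0.85, 0.10],  # latissimus dorsi
        [0.16, 0.21, 0.62, 0.15],  # trapezius
    ]
)

# Control-pre activation timing: bump peak time (cycle fraction) and the
# 20%-of-peak crossing span (equals the activation duration T at the 20%
# threshold convention).
_TMAX_CONTROL_PRE = (0.27, 0.39, 0.44, 0.70)
_T_CONTROL_PRE = (0.37, 0.61, 0.54, 0.68)

# Four phase durations as fractions of the cycle (leg-retraction,
# leg-flipping, pedal-clamp, glide); a 1.4 s cycle split 0.4/0.2/0.3/0.5 s.
_PHASE_FRACTIONS = (0.4 / 1.4, 0.2 / 1.4, 0.3 / 1.4, 0.5 / 1.4)

# exp(-d^2 / 2 sigma^2) = 0.2  at  d = sigma * sqrt(2 ln 5)
_GAUSS_20PCT_HALFSPAN = float(np.sqrt(2.0 * np.log(5.0)))
_LN5 = float(np.log(5.0))


@dataclass(frozen=True)
class Bump:
    """One synergy's activation bump on the periodic cycle-fraction axis.

    ``width`` is the 20%-of-peak crossing span (for the smooth shapes) or
    the full support (for the rectangular shape); both interpreted
    circularly, since the stroke cycle is periodic.  Shapes:

    * ``gaussian`` -- plain Gaussian, sigma set by the 20% span;
    * ``plateau`` -- flat-topped super-Gaussian ``exp(-ln5 (2d/width)^p)``
      (steepness ``p``), for activations that persist through a phase and
      then decline;
    * ``peaked`` -- a sharp Gaussian core of 20%-span ``core_width`` riding
      on a low flat shoulder of height ``shoulder`` that decays through 0.2
      exactly at ``width/2``, for activations that rise rapidly to a peak
      but stay weakly active over a longer span;
    * ``rect`` -- indicator of the support, for exact closed-form tests.

    All smooth shapes have their 20%-of-peak crossings at ``center ±
    width/2`` and a unique maximum at ``center``.
    """

    center: float
    width: float
    amplitude: float = 1.0
    shape: Literal["gaussian", "plateau", "peaked", "rect"] = "gaussian"
    p: float = 8.0  # plateau steepness
    core_width: float = 0.18  # peaked: 20% span of the core
    shoulder: float = 0.3  # peaked: shoulder height (0.2 < shoulder < 1)

    def __post_init__(self) -> None:
        if not 0 <= self.center < 1:
            raise ValueError(f"bump center must lie in [0, 1), got {self.center}")
        if self.width <= 0:
            raise ValueError("bump width must be positive")
        if self.shape == "peaked" and not 0.2 < self.shoulder < 1.0:
            raise ValueError("peaked shoulder must lie in (0.2, 1)")

    def evaluate(self, grid: np.ndarray) -> np.ndarray:
        """Bump values at cycle fractions ``grid`` (wrapped distance)."""
        off = np.asarray(grid, dtype=float) - self.center
        off = (off + 0.5) % 1.0 - 0.5  # signed circular offset
        d = np.abs(off)
        if self.shape == "rect":
            # half-open support [center - w/2, center + w/2)
            return np.where(
                (off >= -self.width / 2.0) & (off < self.width / 2.0),
                self.amplitude,
                0.0,
            )
        if self.shape == "gaussian":
            sigma = self.width / (2.0 * _GAUSS_20PCT_HALFSPAN)
            return self.amplitude * np.exp(-0.5 * (d / sigma) ** 2)
        if self.shape == "plateau":
            return self.amplitude * np.exp(-_LN5 * (2.0 * d / self.width) ** self.p)
        if self.shape == "peaked":
            core = np.exp(-_LN5 * (2.0 * d / self.core_width) ** 2)
            sh = self.shoulder * np.exp(
                -np.log(self.shoulder / 0.2) * (2.0 * d / self.width) ** 8
            )
            return self.amplitude * np.maximum(core, sh)
        raise ValueError(f"unknown bump shape {self.shape!r}")


@dataclass
class GroundTruth:
    """Known synergy structure a synthetic cohort is generated from.

    ``weights`` holds the per-muscle mean weights on their published scale;
    ``weights_normalized`` rescales each column to max 1 (the convention of
    the extraction stage) and is what the synthesizer uses.
    """

    weights: np.ndarray  # m x k
    timing: tuple[Bump, ...]  # one per synergy
    phase_fractions: tuple[float, ...] = _PHASE_FRACTIONS
    muscle_labels: tuple[str, ...] = MUSCLES

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights < 0):
            raise ValueError("ground-truth weights must be non-negative")
        if self.weights.shape[1] != len(self.timing):
            raise ValueError("one timing bump required per synergy")
        if self.weights.shape[0] != len(self.muscle_labels):
            raise ValueError("weights rows must match muscle labels")
        pf = np.asarray(self.phase_fractions, dtype=float)
        if np.any(pf <= 0) or abs(pf.sum() - 1.0) > 1e-9:
            raise ValueError("phase fractions must be positive and sum to 1")

    @property
    def k_true(self) -> int:
        return self.weights.shape[1]

    @property
    def weights_normalized(self) -> np.ndarray:
        """Weights with each synergy column rescaled to max exactly 1."""
        colmax = self.weights.max(axis=0)
        if np.any(colmax <= 0):
            raise ValueError("cannot normalize an all-zero synergy column")
        return self.weights / colmax

    def copy(self) -> "GroundTruth":
        return GroundTruth(
            self.weights.copy(),
            tuple(self.timing),
            tuple(self.phase_fractions),
            tuple(self.muscle_labels),
        )


def default_ground_truth() -> GroundTruth:
    """The four-synergy control-group pre-intervention structure.

    Weights are the published per-muscle means; timing bumps peak at the
    published peak moments (0.27, 0.39, 0.44, 0.70 of the cycle) and their
    20%-of-peak spans equal the published activation durations (0.37, 0.61,
    0.54, 0.68).  Shapes follow the described waveforms: the leg-retraction
    synergy (SYN1) rises rapidly to a sharp peak over a weakly active span;
    the tibialis-anterior synergy (SYN2) plateaus through the pedal-clamp
    stage; the trunk synergy (SYN3) has a concentrated peak within a longer
    low-level span; the glide synergy (SYN4) is a broad flat-topped burst.
    """
    c1, c2, c3, c4 = _TMAX_CONTROL_PRE
    t1, t2, t3, t4 = _T_CONTROL_PRE
    bumps = (
        Bump(center=c1, width=t1, shape="peaked", core_width=0.18, shoulder=0.30),
        Bump(center=c2, width=t2, shape="plateau", p=8.0),
        Bump(center=c3, width=t3, shape="peaked", core_width=0.16, shoulder=0.25),
        Bump(center=c4, width=t4, shape="plateau", p=4.0),
    )
    return GroundTruth(weights=_W_CONTROL_PRE.copy(), timing=bumps)


def make_envelope(gt: GroundTruth, grid: np.ndarray) -> np.ndarray:
    """Noise-free activation envelope ``W x H`` at cycle fractions ``grid``."""
    grid = np.asarray(grid, dtype=float)
    H = np.vstack([b.evaluate(grid) for b in gt.timing])  # k x n
    return gt.weights_normalized @ H


# ---------------------------------------------------------------------------
# cohort specification and effect injection


@dataclass(frozen=True)
class EffectInjection:
    """An additive/multiplicative change to one ground-truth parameter of one
    group x session cell.

    kind:
      * ``weight`` -- add ``delta`` to ``weights[muscle, synergy]`` (clipped
        at 0 from below);
      * ``timing`` -- add ``delta`` to a bump parameter
        (``param`` in {center, width});
      * ``iemg`` -- multiply the named muscle's envelope by ``1 + delta``
        inside one phase.
    """

    group: str
    session: str
    kind: Literal["weight", "timing", "iemg"]
    synergy: str | None = None
    muscle: str | None = None
    param: str | None = None
    phase: str | None = None
    delta: float = 0.0

    def __post_init__(self) -> None:
        if self.group not in GROUPS or self.session not in SESSIONS:
            raise ValueError(f"unknown cell ({self.group}, {self.session})")
        if self.kind == "weight" and (self.synergy is None or self.muscle is None):
            raise ValueError("weight injection needs synergy and muscle")
        if self.kind == "timing" and (
            self.synergy is None or self.param not in ("center", "width")
        ):
            raise ValueError("timing injection needs synergy and param")
        if self.kind == "iemg" and (self.muscle is None or self.phase is None):
            raise ValueError("iemg injection needs muscle and phase")


@dataclass
class CohortSpec:
    """Study-design parameters for a synthetic cohort.

    Defaults mirror the study conditions: 15 subjects per group, pre and
    post sessions, 2000 Hz sampling, 1.4 s stroke cycles, five cycles per
    trial (the published minimum), envelope-to-noise amplitude ratio 10.
    """

    subjects_per_group: int = 15
    cycles_per_trial: int = 5
    cycle_s: float = 1.4
    fs: float = 2000.0
    snr: float = 10.0
    amplitude_uv: float = 200.0
    weight_jitter_sigma: float = 0.15  # log-normal, per subject
    timing_jitter_sigma: float = 0.03  # additive on centers, cycle fractions
    session_jitter_sigma: float = 0.10  # log-normal measurement-level scatter
    carrier_band_hz: tuple[float, float] = (20.0, 400.0)
    #: amplitude (relative to each channel's envelope peak) of smooth
    #: synergy-unmodeled muscle activity, drawn independently per channel
    #: and cycle; emulates the variance real envelopes carry beyond the
    #: modular structure, which sets the operating point of the VAF
    #: model-order criterion.
    residual_activity: float = 0.31
    #: correlation length (burst time scale) of that activity, in seconds
    residual_corr_s: float = 0.06
    effects: tuple[EffectInjection, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.subjects_per_group < 1 or self.cycles_per_trial < 1:
            raise ValueError("counts must be >= 1")
        if self.fs <= 0 or self.cycle_s <= 0:
            raise ValueError("fs and cycle_s must be positive")
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        if self.residual_activity < 0 or self.residual_corr_s <= 0:
            raise ValueError("residual activity/corr must be non-negative/positive")


def _apply_injections(
    gt: GroundTruth, spec: CohortSpec, group: str, session: str
) -> tuple[GroundTruth, dict[tuple[str, str], float]]:
    """Return the cell's ground truth with injections applied, plus per
    (muscle, phase) envelope gain factors."""
    out = gt.copy()
    gains: dict[tuple[str, str], float] = {}
    bumps = list(out.timing)
    for eff in spec.effects:
        if (eff.group, eff.session) != (group, session):
            continue
        if eff.kind == "weight":
            j = _index(SYNERGY_NAMES[: gt.k_true], eff.synergy, "synergy")
            i = _index(gt.muscle_labels, eff.muscle, "muscle")
            out.weights[i, j] = max(0.0, out.weights[i, j] + eff.delta)
        elif eff.kind == "timing":
            j = _index(SYNERGY_NAMES[: gt.k_true], eff.synergy, "synergy")
            b = bumps[j]
            if eff.param == "center":
                bumps[j] = dataclasses.replace(b, center=(b.center + eff.delta) % 1.0)
            else:
                bumps[j] = dataclasses.replace(b, width=max(1e-3, b.width + eff.delta))
        elif eff.kind == "iemg":
            _index(gt.muscle_labels, eff.muscle, "muscle")
            if eff.phase not in PHASES:
                raise ValueError(f"unknown phase {eff.phase!r}")
            gains[(eff.muscle, eff.phase)] = gains.get(
                (eff.muscle, eff.phase), 1.0
            ) * (1.0 + eff.delta)
    out.timing = tuple(bumps)
    return out, gains


def _index(labels, name, what) -> int:
    try:
        return list(labels).index(name)
    except ValueError:
        raise ValueError(f"unknown {what} {name!r}; expected one of {list(labels)}")


# ---------------------------------------------------------------------------
# signal synthesis


def _subject_rng(spec: CohortSpec, subject_idx: int, group: str, tag: int) -> np.random.Generator:
    g = GROUPS.index(group)
    return np.random.default_rng(
        np.random.SeedSequence((spec.seed, g, subject_idx, tag))
    )


def _session_rng(
    spec: CohortSpec, subject_idx: int, group: str, session: str
) -> np.random.Generator:
    g = GROUPS.index(group)
    s = SESSIONS.index(session)
    return np.random.default_rng(
        np.random.SeedSequence((spec.seed, g, subject_idx, 100 + s))
    )


def _jittered_ground_truth(
    gt: GroundTruth, spec: CohortSpec, subject_idx: int, group: str
) -> GroundTruth:
    """Per-subject structure: log-normal weight jitter, additive timing jitter.

    Seeded by (cohort seed, group, subject) only, so a subject carries the
    same idiosyncratic structure into both sessions -- the repeated-measures
    design's subject effect.
    """
    rng = _subject_rng(spec, subject_idx, group, tag=999)
    out = gt.copy()
    # jitter the max-1-normalized weights and keep them as-is: a subject's
    # dominant muscles scatter around 1 rather than being pinned there
    out.weights = gt.weights_normalized * rng.lognormal(
        mean=0.0, sigma=spec.weight_jitter_sigma, size=out.weights.shape
    )
    bumps = []
    for b in out.timing:
        c = (b.center + rng.normal(0.0, spec.timing_jitter_sigma)) % 1.0
        bumps.append(dataclasses.replace(b, center=c))
    out.timing = tuple(bumps)
    return out


def _band_limited_carrier(
    rng: np.random.Generator, n: int, fs: float, band: tuple[float, float]
) -> np.ndarray:
    """Zero-mean, unit-variance Gaussian noise band-limited to ``band``."""
    x = rng.standard_normal(n)
    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, x)
    sd = x.std()
    return x / sd if sd > 0 else x


def _smooth_activity(
    rng: np.random.Generator, n: int, fs: float, corr_len_s: float
) -> np.ndarray:
    """Non-negative smooth random activity with unit standard deviation.

    Rectified low-pass-filtered Gaussian noise; ``corr_len_s`` sets the
    burst time scale.
    """
    x = rng.standard_normal(n)
    sos = sps.butter(2, 1.0 / corr_len_s, fs=fs, output="sos")
    x = np.abs(sps.sosfiltfilt(sos, x))
    sd = x.std()
    return x / sd if sd > 0 else x


def _events_for(spec: CohortSpec, gt: GroundTruth) -> CycleEvents:
    rows = []
    pf = np.asarray(gt.phase_fractions)
    for c in range(spec.cycles_per_trial):
        t0 = c * spec.cycle_s
        edges = t0 + np.concatenate([[0.0], np.cumsum(pf)]) * spec.cycle_s
        for p, phase in enumerate(PHASES):
            rows.append(
                {
                    "cycle": c + 1,
                    "phase": phase,
                    "start_s": edges[p],
                    "end_s": edges[p + 1],
                }
            )
    return CycleEvents(pd.DataFrame(rows))


def synthesize_recording(
    gt: GroundTruth,
    spec: CohortSpec,
    subject: str,
    group: str,
    session: str,
    subject_idx: int | None = None,
) -> tuple[EmgRecording, CycleEvents]:
    """Simulate one trial's raw EMG plus its phase events.

    The raw signal per channel is ``amplitude_uv * envelope(t) * carrier(t)
    + noise(t)`` with a 20-400 Hz unit-variance Gaussian carrier and white
    noise of amplitude ``envelope_peak / snr``.  The envelope is the
    synergy model ``W x H`` plus smooth synergy-unmodeled activity of
    relative amplitude ``residual_activity``, drawn fresh per channel and
    cycle.  Deterministic given (spec.seed, subject, group, session).
    """
    if subject_idx is None:
        subject_idx = abs(hash(subject)) % (2**31)
    cell_gt, gains = _apply_injections(gt, spec, group, session)
    subj_gt = _jittered_ground_truth(cell_gt, spec, subject_idx, group)

    n_cycle = int(round(spec.cycle_s * spec.fs))
    grid = np.arange(n_cycle) / n_cycle  # cycle fractions, half-open [0, 1)
    # jittered weights enter the forward model unrenormalized
    H_true = np.vstack([b.evaluate(grid) for b in subj_gt.timing])
    env_cycle = subj_gt.weights @ H_true  # m x n_cycle

    # per-phase channel gain injections (iemg targets)
    if gains:
        edges = np.concatenate([[0.0], np.cumsum(subj_gt.phase_fractions)])
        for (muscle, phase), gain in gains.items():
            i = _index(subj_gt.muscle_labels, muscle, "muscle")
            p = PHASES.index(phase)
            mask = (grid >= edges[p]) & (grid < edges[p + 1])
            env_cycle[i, mask] *= gain

    m = env_cycle.shape[0]
    rng = _session_rng(spec, subject_idx, group, session)
    cycles = []
    for _ in range(spec.cycles_per_trial):
        e = env_cycle.copy()
        if spec.residual_activity > 0:
            for i in range(m):
                e[i] += (
                    spec.residual_activity
                    * e[i].max()
                    * _smooth_activity(rng, n_cycle, spec.fs, spec.residual_corr_s)
                )
        cycles.append(e)
    env = np.hstack(cycles)
    n = env.shape[1]

    signal = np.empty_like(env)
    for i in range(m):
        carrier = _band_limited_carrier(rng, n, spec.fs, spec.carrier_band_hz)
        peak = env[i].max()
        noise_amp = peak / spec.snr if peak > 0 else 1.0 / spec.snr
        noise = rng.standard_normal(n) * noise_amp
        signal[i] = spec.amplitude_uv * (env[i] * carrier + noise)

    rec = EmgRecording(
        muscle_labels=list(subj_gt.muscle_labels),
        fs=spec.fs,
        signal=signal,
        meta=TrialMeta(subject=subject, group=group, session=session),
    )
    return rec, _events_for(spec, subj_gt)


@dataclass
class CohortMember:
    subject: str
    group: str
    session: str
    recording: EmgRecording
    events: CycleEvents
    ground_truth: GroundTruth  # cell-level truth (injections applied, no jitter)


def synthesize_cohort(
    spec: CohortSpec, gt: GroundTruth | None = None
) -> Iterator[CohortMember]:
    """Yield one recording per subject x session across both groups.

    Cell-level ground truth (with that cell's injections applied) is
    attached to every member for recovery testing.
    """
    if gt is None:
        gt = default_ground_truth()
    for group in GROUPS:
        prefix = "E" if group == "experimental" else "C"
        for s_idx in range(spec.subjects_per_group):
            subject = f"{prefix}{s_idx + 1:02d}"
            for session in SESSIONS:
                cell_gt, _ = _apply_injections(gt, spec, group, session)
                rec, events = synthesize_recording(
                    gt, spec, subject, group, session, subject_idx=s_idx
                )
                yield CohortMember(subject, group, session, rec, events, cell_gt)


# ---------------------------------------------------------------------------
# parameter-level measure sampling (statistics calibration harness)


def sample_measure_table(
    spec: CohortSpec,
    gt: GroundTruth | None = None,
    target: EffectInjection | None = None,
    measure_name: str = "measure",
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw a tidy per-subject measure table straight from the generator's
    parameter model, without synthesizing raw signals.

    For a ``weight`` target the measure is the ground-truth weight of that
    (muscle, synergy) -- per cell, injections applied -- multiplied by the
    subject's log-normal jitter (shared across sessions) and a per-session
    log-normal measurement scatter.  For a ``timing`` target the jitters are
    additive Gaussians.  This is the model the full signal pipeline
    estimates; sampling it directly makes large-replicate calibration and
    power studies of the statistics stage feasible.
    """
    if gt is None:
        gt = default_ground_truth()
    if target is None:
        target = EffectInjection(
            group="experimental",
            session="post",
            kind="weight",
            synergy="SYN4",
            muscle="biceps-femoris",
            delta=0.0,
        )
    if rng is None:
        rng = np.random.default_rng(spec.seed)

    rows = []
    for group in GROUPS:
        prefix = "E" if group == "experimental" else "C"
        for s_idx in range(spec.subjects_per_group):
            subject = f"{prefix}{s_idx + 1:02d}"
            if target.kind == "weight":
                subj_jit = rng.lognormal(0.0, spec.weight_jitter_sigma)
            else:
                subj_jit = rng.normal(0.0, spec.timing_jitter_sigma)
            for session in SESSIONS:
                cell_gt, _ = _apply_injections(gt, spec, group, session)
                if target.kind == "weight":
                    j = _index(SYNERGY_NAMES[: gt.k_true], target.synergy, "synergy")
                    i = _index(gt.muscle_labels, target.muscle, "muscle")
                    base = cell_gt.weights[i, j]
                    value = (
                        base
                        * subj_jit
                        * rng.lognormal(0.0, spec.session_jitter_sigma)
                    )
                elif target.kind == "timing":
                    j = _index(SYNERGY_NAMES[: gt.k_true], target.synergy, "synergy")
                    b = cell_gt.timing[j]
                    base = b.center if target.param == "center" else b.width
                    value = (
                        base
                        + subj_jit
                        + rng.normal(0.0, spec.timing_jitter_sigma / 2.0)
                    )
                else:
                    raise ValueError(
                        "measure sampling supports weight and timing targets"
                    )
                rows.append(
                    {
                        "subject": subject,
                        "group": group,
                        "session": session,
                        "measure": measure_name,
                        "value": value,
                    }
                )
    return pd.DataFrame(rows)
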