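"""From raw per-trial grasp-lift recordings to the non-negative 5-way tensor.

The processing chain mirrors standard grasp-lift kinetics/EMG practice:

1. load force from object mass and airborne acceleration,
   ``LF = m * sqrt((a_z + g)^2 + a_y^2)``;
2. 4th-order low-pass Butterworth filtering (12 Hz for forces, 10 Hz
   zero-phase for rectified EMG);
3. full-wave rectification and down-sampling of EMG to the kinematic rate;
4. lift-window detection: first contact when grip force exceeds 0.1 N,
   stable hold when vertical velocity falls back below 0.001 m/s after the
   lift, padded by 100 ms on both sides;
5. time normalization of every channel to 500 samples and removal of 20
   edge samples (filter transients), leaving 460;
6. per-participant EMG amplitude normalization (each muscle divided by its
   maximum over all of that participant's trials);
7. assembly into the tensor X (channels x time x object x participant x
   trial) with participants ordered by age, and a single-scalar rescaling of
   the force channels so forces and EMG have the same mean l2-norm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import signal as sps

__all__ = [
    "CHANNEL_NAMES",
    "N_FORCE_CHANNELS",
    "EMG_CHANNEL_NAMES",
    "TrialRecording",
    "LiftWindow",
    "MotorTensor",
    "LiftDetectionError",
    "DegenerateChannelError",
    "TensorAssemblyError",
    "compute_load_force",
    "lowpass_filter",
    "rectify_emg",
    "downsample",
    "detect_lift_window",
    "time_normalize",
    "trim_edges",
    "normalize_emg_per_participant",
    "flag_amplitude_outliers",
    "process_trial",
    "assemble_tensor",
    "balance_modalities",
    "preprocess_dataset",
]

#: Spatial-mode channel order: indices 1-4 are forces, 5-12 are muscles
#: (right/left pairs of anterior deltoid, extensor carpi radialis, flexor
#: carpi radialis, abductor pollicis brevis).
CHANNEL_NAMES: tuple[str, ...] = (
    "Grip force (right)",
    "Grip force (left)",
    "Load force (right)",
    "Load force (left)",
    "Anterior deltoid (right)",
    "Anterior deltoid (left)",
    "Extensor carpi radialis (right)",
    "Extensor carpi radialis (left)",
    "Flexor carpi radialis (right)",
    "Flexor carpi radialis (left)",
    "Abductor pollicis brevis (right)",
    "Abductor pollicis brevis (left)",
)
N_FORCE_CHANNELS = 4
EMG_CHANNEL_NAMES: tuple[str, ...] = CHANNEL_NAMES[N_FORCE_CHANNELS:]

OBJECT_LABELS: tuple[str, str] = ("heavy", "light")  # j = 0 heavy, j = 1 light

GRAVITY = 9.81  # m/s^2


class LiftDetectionError(RuntimeError):
    """Lift-phase events could not be located in a trial."""


class DegenerateChannelError(ValueError):
    """An EMG channel is identically zero and cannot be max-normalized."""


class TensorAssemblyError(ValueError):
    """The (participant, object, trial) grid has missing cells."""

    def __init__(self, missing: list[tuple]):
        self.missing = missing
        preview = ", ".join(map(str, missing[:5]))
        more = "" if len(missing) <= 5 else f" (+{len(missing) - 5} more)"
        super().__init__(f"missing trial cells: {preview}{more}")


@dataclass
class TrialRecording:
    """Raw signals of one grasp-lift-replace trial.

    Kinetic/kinematic channels are sampled at ``fs_kin`` (Hz), the 8 EMG
    channels at ``fs_emg``; ``annotations`` may carry ground-truth event
    samples (synthetic data only).
    """

    participant_id: int
    object_label: str          # "heavy" | "light"
    trial_index: int           # 0-based, 0..K-1
    mass: float                # kg
    gf_r: np.ndarray           # grip force, right hand (N)
    gf_l: np.ndarray           # grip force, left hand (N)
    a_z: np.ndarray            # vertical object acceleration (m/s^2)
    a_y: np.ndarray            # sagittal object acceleration (m/s^2)
    vel_z: np.ndarray          # vertical object velocity (m/s)
    emg: np.ndarray            # (8, n_emg) raw EMG (V)
    fs_kin: float = 200.0
    fs_emg: float = 2000.0
    g: float = GRAVITY
    annotations: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.object_label not in OBJECT_LABELS:
            raise ValueError(f"unknown object label {self.object_label!r}")
        n_kin = len(self.gf_r)
        for name in ("gf_l", "a_z", "a_y", "vel_z"):
            if len(getattr(self, name)) != n_kin:
                raise ValueError(f"kinematic channel {name} length mismatch")
        if self.emg.shape[0] != len(EMG_CHANNEL_NAMES):
            raise ValueError(f"expected {len(EMG_CHANNEL_NAMES)} EMG channels, "
                             f"got {self.emg.shape[0]}")
        ratio = self.fs_emg / self.fs_kin
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("fs_emg must be an integer multiple of fs_kin")


@dataclass
class LiftWindow:
    """Detected lift phase of one trial (sample indices at the kinematic rate).

    The analysis window spans ``[start, stop]`` inclusive: 100 ms before the
    first contact through 100 ms after the beginning of the stable hold.
    """

    first_contact_idx: int
    stable_onset_idx: int
    start: int
    stop: int
    gf_threshold: float = 0.1      # N
    vel_threshold: float = 0.001   # m/s
    pad_ms: float = 100.0


@dataclass
class MotorTensor:
    """The 5-way non-negative array X (channel x time x object x participant
    x trial) with its index maps."""

    X: np.ndarray
    channel_names: tuple[str, ...] = CHANNEL_NAMES
    participant_ids: tuple[int, ...] = ()
    object_labels: tuple[str, str] = OBJECT_LABELS
    attrs: dict = field(default_factory=dict)

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 5:
            raise ValueError(f"expected a 5-way array, got {self.X.ndim} modes")
        if np.any(self.X < 0):
            raise ValueError("tensor entries must be non-negative")
        if self.X.shape[0] != len(self.channel_names):
            raise ValueError("channel axis does not match channel_names")
        if self.participant_ids and self.X.shape[3] != len(self.participant_ids):
            raise ValueError("participant axis does not match participant_ids")


# ---------------------------------------------------------------------------
# Elementary signal operations
# ---------------------------------------------------------------------------

def compute_load_force(m: float, a_z, a_y, g: float = GRAVITY) -> np.ndarray:
    """Load force of an airborne object: ``m * sqrt((a_z + g)^2 + a_y^2)``."""
    if m <= 0:
        raise ValueError(f"mass must be positive, got {m}")
    a_z = np.asarray(a_z, dtype=float)
    a_y = np.asarray(a_y, dtype=float)
    if a_z.shape != a_y.shape:
        raise ValueError("a_z and a_y must have equal length")
    return m * np.sqrt((a_z + g) ** 2 + a_y**2)


def lowpass_filter(x, cutoff: float, fs: float, order: int = 4,
                   zero_phase: bool = True) -> np.ndarray:
    """Low-pass Butterworth filter (``order`` poles, ``cutoff`` Hz).

    With ``zero_phase`` the filter runs forward and backward (no phase lag;
    the magnitude response is applied twice).
    """
    if not 0 < cutoff < fs / 2:
        raise ValueError(
            f"cutoff must lie in (0, fs/2) = (0, {fs / 2}), got {cutoff}")
    sos = sps.butter(order, cutoff, btype="low", fs=fs, output="sos")
    x = np.asarray(x, dtype=float)
    if zero_phase:
        return sps.sosfiltfilt(sos, x, axis=-1)
    return sps.sosfilt(sos, x, axis=-1)


def rectify_emg(x) -> np.ndarray:
    """Full-wave rectification (elementwise absolute value)."""
    return np.abs(np.asarray(x, dtype=float))


def downsample(x, fs_in: float, fs_out: float) -> np.ndarray:
    """Keep every (fs_in/fs_out)-th sample, starting at sample 0.

    The input is assumed to be low-pass filtered well below the output
    Nyquist rate already, so plain decimation is alias-free.
    """
    ratio = fs_in / fs_out
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError(
            f"fs_in/fs_out must be an integer, got {fs_in}/{fs_out}")
    step = int(round(ratio))
    return np.asarray(x, dtype=float)[..., ::step]


def detect_lift_window(gf, vel_z, fs: float, gf_threshold: float = 0.1,
                       vel_threshold: float = 0.001,
                       pad_ms: float = 100.0) -> LiftWindow:
    """Locate the dynamic lift phase from grip force and vertical velocity.

    First contact is the first sample with ``gf > gf_threshold``; the stable
    hold begins at the first sample after the peak of ``|vel_z|`` where
    ``|vel_z| < vel_threshold``.  The returned window is padded by ``pad_ms``
    on both sides and must fit inside the recording.
    """
    gf = np.asarray(gf, dtype=float)
    vel_z = np.asarray(vel_z, dtype=float)
    if gf.shape != vel_z.shape:
        raise ValueError("gf and vel_z must be aligned (equal length)")
    above = np.flatnonzero(gf > gf_threshold)
    if above.size == 0:
        raise LiftDetectionError(
            f"grip force never exceeded {gf_threshold} N")
    first_contact = int(above[0])
    speed = np.abs(vel_z)
    peak = int(np.argmax(speed))
    below = np.flatnonzero(speed[peak + 1:] < vel_threshold)
    if below.size == 0:
        raise LiftDetectionError(
            f"velocity never returned below {vel_threshold} m/s after the lift")
    stable_onset = peak + 1 + int(below[0])
    if stable_onset <= first_contact:
        raise LiftDetectionError(
            "stable-hold onset precedes first contact; no lift found")
    pad = int(round(pad_ms / 1000.0 * fs))
    start = first_contact - pad
    stop = stable_onset + pad
    if start < 0 or stop >= len(gf):
        raise LiftDetectionError(
            f"padded window [{start}, {stop}] exceeds the recording "
            f"(length {len(gf)})")
    return LiftWindow(first_contact, stable_onset, start, stop,
                      gf_threshold, vel_threshold, pad_ms)


def time_normalize(x, target_len: int = 500) -> np.ndarray:
    """Linearly resample a signal onto ``target_len`` samples spanning its
    original support (endpoints preserved)."""
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    if n < 2:
        raise ValueError(f"need at least 2 samples to resample, got {n}")
    grid = np.linspace(0.0, n - 1.0, target_len)
    support = np.arange(n)
    if x.ndim == 1:
        return np.interp(grid, support, x)
    return np.stack([np.interp(grid, support, row) for row in x])


def trim_edges(x, n_trim: int = 20) -> np.ndarray:
    """Drop ``n_trim`` samples from each end (filter edge artifacts)."""
    x = np.asarray(x)
    n = x.shape[-1]
    if n <= 2 * n_trim:
        raise ValueError(
            f"signal of length {n} too short to trim {n_trim} per edge")
    if n_trim == 0:
        return x.copy()
    return x[..., n_trim:-n_trim].copy()


# ---------------------------------------------------------------------------
# Participant-level normalization and tensor assembly
# ---------------------------------------------------------------------------

def normalize_emg_per_participant(
    emg_trials: Sequence[np.ndarray], participant_id: int | None = None
) -> list[np.ndarray]:
    """Divide every EMG channel by its maximum over all trials of one
    participant (across objects, trials and time), so each channel peaks at 1.
    """
    if len(emg_trials) == 0:
        raise ValueError("need at least one trial")
    stacked = np.stack([np.asarray(t, dtype=float) for t in emg_trials])
    maxima = stacked.max(axis=(0, 2))
    dead = np.flatnonzero(maxima <= 0)
    if dead.size:
        who = "" if participant_id is None else f" of participant {participant_id}"
        raise DegenerateChannelError(
            f"EMG channel(s) {dead.tolist()}{who} are identically zero")
    return [t / maxima[:, None] for t in stacked]


def process_trial(trial: TrialRecording, force_cutoff: float = 12.0,
                  emg_cutoff: float = 10.0, filter_order: int = 4,
                  gf_threshold: float = 0.1, vel_threshold: float = 0.001,
                  pad_ms: float = 100.0, t0: int = 500,
                  n_trim: int = 20) -> np.ndarray:
    """Run one trial through the full single-trial chain.

    Returns the 12 x (t0 - 2*n_trim) channel matrix in the spatial-mode
    order (grip R/L, load R/L, then the 8 EMG envelopes), *before*
    per-participant EMG normalization and modality balancing.  Filtered
    envelopes are clipped at zero (zero-phase filtering can undershoot).
    """
    lf = compute_load_force(trial.mass, trial.a_z, trial.a_y, trial.g)
    forces = np.stack([trial.gf_r, trial.gf_l, lf, lf])
    forces = lowpass_filter(forces, force_cutoff, trial.fs_kin,
                            order=filter_order, zero_phase=True)
    env = lowpass_filter(rectify_emg(trial.emg), emg_cutoff, trial.fs_emg,
                         order=filter_order, zero_phase=True)
    env = downsample(env, trial.fs_emg, trial.fs_kin)
    n = min(forces.shape[-1], env.shape[-1])
    # Contact detection uses whichever hand touches first.
    gf_any = np.maximum(forces[0, :n], forces[1, :n])
    window = detect_lift_window(gf_any, trial.vel_z[:n], trial.fs_kin,
                                gf_threshold, vel_threshold, pad_ms)
    sl = slice(window.start, window.stop + 1)
    channels = np.vstack([forces[:, :n][:, sl], env[:, :n][:, sl]])
    channels = trim_edges(time_normalize(channels, t0), n_trim)
    return np.clip(channels, 0.0, None)


def assemble_tensor(
    cells: Mapping[tuple[int, str, int], np.ndarray],
    participants: Sequence,
    n_trials: int | None = None,
) -> MotorTensor:
    """Collate per-trial channel matrices into the 5-way tensor.

    ``cells`` maps ``(participant_id, object_label, trial_index)`` to a
    (channels x time) matrix.  Participants are ordered by ascending age
    (from the metadata sequence, which must expose ``participant_id`` and
    ``age``); objects are ordered heavy then light.  The arrival order of
    ``cells`` is irrelevant.  A missing cell raises
    :class:`TensorAssemblyError` listing the absent (p, j, k) indices.
    """
    meta = sorted(participants, key=lambda m: (m.age, m.participant_id))
    pids = [m.participant_id for m in meta]
    if n_trials is None:
        n_trials = 1 + max(k for (_, _, k) in cells.keys())
    sample = next(iter(cells.values()))
    m_ch, n_t = np.asarray(sample).shape
    X = np.empty((m_ch, n_t, len(OBJECT_LABELS), len(pids), n_trials))
    missing: list[tuple] = []
    for p, pid in enumerate(pids):
        for j, obj in enumerate(OBJECT_LABELS):
            for k in range(n_trials):
                cell = cells.get((pid, obj, k))
                if cell is None:
                    missing.append((pid, obj, k))
                    continue
                cell = np.asarray(cell, dtype=float)
                if cell.shape != (m_ch, n_t):
                    raise ValueError(
                        f"cell {(pid, obj, k)} has shape {cell.shape}, "
                        f"expected {(m_ch, n_t)}")
                X[:, :, j, p, k] = cell
    if missing:
        raise TensorAssemblyError(missing)
    names = CHANNEL_NAMES if m_ch == len(CHANNEL_NAMES) else tuple(
        f"channel_{i + 1}" for i in range(m_ch))
    return MotorTensor(X, channel_names=names, participant_ids=tuple(pids))


def balance_modalities(mt: MotorTensor,
                       n_force: int = N_FORCE_CHANNELS) -> MotorTensor:
    """Rescale the force channels by one scalar so the mean l2-norm of the
    force rows of the mode-1 unfolding equals that of the EMG rows.

    Within-group relative strengths are untouched; applying the operation
    twice is a no-op.
    """
    X = mt.X
    flat = X.reshape(X.shape[0], -1)
    row_norms = np.linalg.norm(flat, axis=1)
    force_mean = row_norms[:n_force].mean()
    emg_mean = row_norms[n_force:].mean()
    if force_mean == 0 or emg_mean == 0:
        raise DegenerateChannelError(
            "a whole modality (forces or EMG) is zero; cannot balance")
    scale = emg_mean / force_mean
    Xb = X.copy()
    Xb[:n_force] *= scale
    attrs = dict(mt.attrs)
    attrs["force_scale"] = attrs.get("force_scale", 1.0) * scale
    return MotorTensor(Xb, channel_names=mt.channel_names,
                       participant_ids=mt.participant_ids,
                       object_labels=mt.object_labels, attrs=attrs)


def flag_amplitude_outliers(channels: np.ndarray, z_max: float = 8.0):
    """Channels whose peak is an extreme amplitude outlier (|z| > z_max
    within the channel).  Advisory only — artifact rejection is a judgment
    call, so callers warn and never drop trials automatically."""
    mu = channels.mean(axis=-1, keepdims=True)
    sd = channels.std(axis=-1, keepdims=True)
    sd[sd == 0] = np.inf
    z = (channels - mu) / sd
    return np.flatnonzero(np.abs(z).max(axis=-1) > z_max)


def preprocess_dataset(trials: Iterable[TrialRecording], participants,
                       **kwargs) -> MotorTensor:
    """Full preprocessing: per-trial chain, per-participant EMG
    normalization, tensor assembly and modality balancing."""
    import warnings

    per_participant: dict[int, list[TrialRecording]] = {}
    for tr in trials:
        per_participant.setdefault(tr.participant_id, []).append(tr)
    cells: dict[tuple[int, str, int], np.ndarray] = {}
    n_trials = 0
    for pid, trs in per_participant.items():
        mats = []
        for t in trs:
            try:
                mat = process_trial(t, **kwargs)
            except (LiftDetectionError, ValueError) as exc:
                raise type(exc)(
                    f"participant {t.participant_id}, {t.object_label} "
                    f"object, trial {t.trial_index}: {exc}") from exc
            bad = flag_amplitude_outliers(mat)
            if bad.size:
                warnings.warn(
                    f"possible artifact: channel(s) {bad.tolist()} of "
                    f"participant {t.participant_id}, {t.object_label} "
                    f"object, trial {t.trial_index} have |z| > 8 samples",
                    stacklevel=2)
            mats.append(mat)
        emg_norm = normalize_emg_per_participant(
            [m[N_FORCE_CHANNELS:] for m in mats], pid)
        for t, mat, emg in zip(trs, mats, emg_norm):
            cells[(pid, t.object_label, t.trial_index)] = np.vstack(
                [mat[:N_FORCE_CHANNELS], emg])
            n_trials = max(n_trials, t.trial_index + 1)
    tensor = assemble_tensor(cells, participants, n_trials=n_trials)
    return balance_modalities(tensor)
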