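"""Synthetic grasp-lift datasets with known ground truth.

The study conditions being emulated: 29 participants (13 younger adults
under 30, 16 older adults over 60), two object masses (0.2 and 0.4 kg),
10 trials per object, 12 spatial channels (4 forces + 8 muscles), EMG at
2000 Hz and kinematics at 200 Hz.  The generators plant a low-rank
non-negative factor structure with controllable age-group effects on a
designated participant-factor column, a linear trend on a designated
trial-factor column, and a negative coupling between the participant
loadings and a manual-dexterity (Purdue-Pegboard-like) score, so every
downstream stage — preprocessing, decomposition, and inference — can be
tested against known truth.

All generators are pure functions of their arguments including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .preprocess import (
    EMG_CHANNEL_NAMES,
    MotorTensor,
    TrialRecording,
)
from .tensorfact import FactorModel, reconstruct

__all__ = [
    "ParticipantMeta",
    "SyntheticGroundTruth",
    "generate_participants",
    "generate_planted_model",
    "generate_tensor_dataset",
    "generate_raw_trials",
]

#: Index (0-based) of the participant- and trial-factor column carrying the
#: planted age-group effect and trial trend.
DESIGNATED_COMPONENT = 0


@dataclass
class ParticipantMeta:
    """Demographics and clinical scores of one participant."""

    participant_id: int
    age: float                 # years
    group: str                 # "YA" (<30) | "OA" (>60)
    pp_score: float            # Purdue-Pegboard-like bimanual dexterity score
    sw_score: float            # summed monofilament target force (grams-force)

    def __post_init__(self):
        if self.group not in ("YA", "OA"):
            raise ValueError(f"unknown group {self.group!r}")
        if self.pp_score <= 0:
            raise ValueError("pp_score must be positive")


@dataclass
class SyntheticGroundTruth:
    """A planted factor model plus the effect sizes used to build it."""

    planted_model: FactorModel
    group_effect_d: float      # standardized OA-YA difference, designated column
    trial_slope: float         # per-trial drift of the designated trial column
    snr_db: float              # target SNR of the emitted tensor (dB)
    seed: int
    n_young: int = 0
    pp_coupling: float = -0.5  # latent correlation of pp_score with loadings


# ---------------------------------------------------------------------------
# Participants
# ---------------------------------------------------------------------------

def generate_participants(n_young: int, n_old: int, pp_coupling: float = -0.5,
                          seed: int = 0) -> list[ParticipantMeta]:
    """Draw participant metadata, sorted by ascending age.

    Ages are uniform on [18, 29] for younger and [60, 85] for older adults.
    ``pp_coupling`` is recorded for later use: the dexterity scores emitted
    here follow only their marginal distribution and are re-coupled to the
    planted participant loadings by :func:`generate_tensor_dataset`.
    """
    if n_young < 2 or n_old < 2:
        raise ValueError("need at least two participants per group")
    if not -1.0 <= pp_coupling <= 0.0:
        raise ValueError("pp_coupling must lie in [-1, 0]")
    rng = np.random.default_rng(seed)
    ages = np.concatenate([
        rng.uniform(18.0, 29.0, size=n_young),
        rng.uniform(60.0, 85.0, size=n_old),
    ])
    groups = ["YA"] * n_young + ["OA"] * n_old
    pp = _pp_marginal(rng.standard_normal(n_young + n_old))
    sw = np.round(rng.uniform(0.4, 4.0, size=n_young + n_old), 2)
    order = np.argsort(ages, kind="stable")
    return [
        ParticipantMeta(
            participant_id=i + 1,
            age=float(round(ages[idx], 1)),
            group=groups[idx],
            pp_score=float(pp[idx]),
            sw_score=float(sw[idx]),
        )
        for i, idx in enumerate(order)
    ]


def _pp_marginal(z: np.ndarray) -> np.ndarray:
    """Map standard-normal latents to a plausible bimanual pin-count scale."""
    return np.maximum(1.0, np.round(14.0 + 2.5 * z, 2))


# ---------------------------------------------------------------------------
# Planted factor models
# ---------------------------------------------------------------------------

def _raised_cosine(T: int, center: float, width: float) -> np.ndarray:
    t = np.arange(T)
    arg = (t - center) / width
    bump = np.where(np.abs(arg) <= 1.0, 0.5 * (1.0 + np.cos(np.pi * arg)), 0.0)
    return bump


def generate_planted_model(dims: tuple[int, int, int, int, int], R: int,
                           group_effect_d: float = 0.0,
                           trial_slope: float = 0.0, seed: int = 0,
                           n_young: int | None = None,
                           pp_coupling: float = -0.5,
                           snr_db: float = np.inf) -> SyntheticGroundTruth:
    """Plant a rank-``R`` non-negative factor model with known structure.

    Spatial columns are sparse (few active channels), temporal columns are
    smooth raised-cosine bumps or monotone ramps, object columns are
    positive, the designated participant column separates the age groups by
    exactly ``group_effect_d`` pooled standard deviations, and the
    designated trial column drifts linearly with slope ``trial_slope``
    (clipped at zero).  Every factor column has unit l2 norm, so all R
    rank-one components contribute equal Frobenius energy.
    """
    if R < 1:
        raise ValueError("rank must be >= 1")
    M, T, J, P, K = dims
    if min(M, T, P, K) < R:
        raise ValueError(
            f"rank {R} exceeds a usable dimension of {dims}")
    if n_young is None:
        n_young = 13 if P == 29 else max(2, round(P * 13 / 29))
    if not 2 <= n_young <= P - 2:
        raise ValueError("need at least two participants per group")
    rng = np.random.default_rng(seed)

    # Spatial: each component recruits its own small group of channels.
    # Supports are disjoint whenever M allows (muscle synergies engage
    # distinct muscle/force groupings), which keeps the planted components
    # linearly independent even though the participant and trial loadings
    # are all-positive and nearly parallel across components.
    A = np.zeros((M, R))
    if M >= 2 * R:
        perm = rng.permutation(M)
        size = M // R
        supports = [perm[r * size:(r + 1) * size] for r in range(R)]
    else:
        supports = [rng.choice(M, size=max(2, M // R), replace=False)
                    for _ in range(R)]
    for r, support in enumerate(supports):
        A[support, r] = rng.uniform(0.6, 1.0, size=len(support))

    # Temporal: smooth raised-cosine activations with staggered centers —
    # the early-centered ones decrease over lift time, mid-centered ones
    # rise then fall.  One family keeps the per-component variance shares
    # comparable (a near-constant profile would contribute mean but almost
    # no variance and become invisible to a VAF criterion).
    B = np.zeros((T, R))
    for r in range(R):
        center = (r + rng.uniform(0.3, 0.7)) / R * (T - 1)
        B[:, r] = _raised_cosine(T, center, 0.3 * T)

    # Object: both objects recruited, mildly unequal balance.
    C = rng.uniform(0.8, 1.2, size=(J, R))

    # Participant: baseline positive loadings; the designated column gets an
    # exact standardized group difference (both groups standardized
    # in-sample, pooled SD 1, then shifted to stay positive).
    D = rng.normal(3.0, 0.5, size=(P, R)).clip(min=0.05)
    ya, oa = slice(0, n_young), slice(n_young, P)
    col = rng.standard_normal(P)
    col[ya] = _standardize(col[ya])
    col[oa] = _standardize(col[oa]) + group_effect_d
    col = 0.5 * col            # within-group SD 0.5, like the other columns
    col += 3.0
    if col.min() < 0.05:       # shift, never clip: clipping would dilute d
        col += 0.05 - col.min()
    D[:, DESIGNATED_COMPONENT] = col

    # Trial: iid positive jitter; the designated column adds a linear drift.
    E = rng.normal(1.0, 0.05, size=(K, R)).clip(min=0.0)
    drift = trial_slope * np.arange(K)
    E[:, DESIGNATED_COMPONENT] = np.clip(
        E[:, DESIGNATED_COMPONENT] + drift, 0.0, None)

    factors = []
    for F in (A, B, C, D, E):
        norms = np.linalg.norm(F, axis=0)
        norms[norms == 0] = 1.0
        factors.append(F / norms)
    model = FactorModel(tuple(factors))
    return SyntheticGroundTruth(
        planted_model=model, group_effect_d=group_effect_d,
        trial_slope=trial_slope, snr_db=snr_db, seed=seed,
        n_young=n_young, pp_coupling=pp_coupling)


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    return (x - x.mean()) / (sd if sd > 0 else 1.0)


# ---------------------------------------------------------------------------
# Tensor datasets
# ---------------------------------------------------------------------------

def generate_tensor_dataset(
    truth: SyntheticGroundTruth, snr_db: float | None = None, seed: int = 0
) -> tuple[MotorTensor, list[ParticipantMeta]]:
    """Emit a noisy tensor from a planted model, plus coupled metadata.

    Gaussian noise is scaled so the variance ratio of signal to noise equals
    ``snr_db`` (the realized pre-clipping SNR is recorded in
    ``MotorTensor.attrs``), then negative entries are clipped to zero.
    Participant dexterity scores are re-drawn through a Gaussian copula so
    their latent correlation with the designated participant loading equals
    ``truth.pp_coupling`` exactly in-sample.
    """
    if snr_db is None:
        snr_db = truth.snr_db
    rng = np.random.default_rng(seed)
    signal = reconstruct(truth.planted_model)
    M, T, J, P, K = signal.shape
    var_s = float(np.var(signal))
    if np.isinf(snr_db):
        X = signal.copy()
        realized = np.inf
    else:
        var_n = var_s / 10.0 ** (snr_db / 10.0)
        noise = rng.normal(0.0, np.sqrt(var_n), size=signal.shape)
        realized = 10.0 * np.log10(var_s / float(np.var(noise)))
        X = np.clip(signal + noise, 0.0, None)

    n_young = truth.n_young
    metas = generate_participants(
        n_young, P - n_young, truth.pp_coupling,
        seed=int(rng.integers(2**31)))
    _couple_pp_scores(metas, truth, rng)

    mt = MotorTensor(
        X,
        channel_names=_default_names(M),
        participant_ids=tuple(m.participant_id for m in metas),
        attrs={
            "snr_db_target": float(snr_db),
            "snr_db_realized": float(realized),
            "planted_rank": truth.planted_model.rank,
            "seed": seed,
        },
    )
    return mt, metas


def _default_names(M: int) -> tuple[str, ...]:
    from .preprocess import CHANNEL_NAMES

    return CHANNEL_NAMES if M == len(CHANNEL_NAMES) else tuple(
        f"channel_{i + 1}" for i in range(M))


def _couple_pp_scores(metas: list[ParticipantMeta],
                      truth: SyntheticGroundTruth, rng) -> None:
    """Gaussian-copula coupling of pp_score to the designated loading.

    The loading column is converted to normal scores via its ranks; an
    independent residual is orthogonalized against those scores in-sample,
    so the realized latent correlation equals the target exactly.  The
    normal marginal of the dexterity score is untouched.
    """
    rho = truth.pp_coupling
    d1 = truth.planted_model.D[:, DESIGNATED_COMPONENT]
    P = len(d1)
    ranks = np.argsort(np.argsort(d1))
    z = norm.ppf((ranks + 1.0) / (P + 1.0))
    z = _standardize(z)
    w = rng.standard_normal(P)
    w = w - z * (w @ z) / (z @ z)          # in-sample orthogonal residual
    w = _standardize(w)
    latent = rho * z + np.sqrt(1.0 - rho**2) * w
    pp = _pp_marginal(latent)
    for meta, score in zip(metas, pp):
        meta.pp_score = float(score)


# ---------------------------------------------------------------------------
# Raw trials
# ---------------------------------------------------------------------------

def generate_raw_trials(meta: list[ParticipantMeta],
                        masses: tuple[float, float] = (0.4, 0.2),
                        trials_per_object: int = 10, fs_emg: float = 2000.0,
                        fs_kin: float = 200.0,
                        seed: int = 0) -> list[TrialRecording]:
    """Simulate raw grasp-lift-replace trials.

    Each trial has a grip-force onset crossing 0.1 N at a known sample, a
    minimum-jerk lift of 0.3 m whose velocity/acceleration profiles are
    analytic, a stable hold with zero velocity, and burst-modulated EMG on
    all 8 channels.  The true first-contact and stable-onset samples (by the
    detection rules: grip force of either hand above 0.1 N; |velocity| below
    0.001 m/s after its peak) are stored in ``annotations``.
    """
    ratio = fs_emg / fs_kin
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError("fs_emg must be an integer multiple of fs_kin")
    if sorted(masses) != [0.2, 0.4]:
        raise ValueError("masses must be the study's 0.2 and 0.4 kg objects")
    rng = np.random.default_rng(seed)
    duration = 4.0
    n_kin = int(round(duration * fs_kin))
    n_emg = int(round(duration * fs_emg))
    t_kin = np.arange(n_kin) / fs_kin
    trials: list[TrialRecording] = []
    mass_label = {0.4: "heavy", 0.2: "light"}
    for m in meta:
        emg_gain = rng.uniform(0.2, 1.0, size=len(EMG_CHANNEL_NAMES))
        for mass in masses:
            label = mass_label[round(mass, 3)]
            for k in range(trials_per_object):
                trials.append(_one_trial(
                    rng, m.participant_id, label, k, mass, t_kin, fs_kin,
                    fs_emg, n_emg, emg_gain))
    return trials


def _min_jerk(t: np.ndarray, t0: float, dur: float, height: float):
    """Minimum-jerk position/velocity/acceleration for a rise of ``height``."""
    s = np.clip((t - t0) / dur, 0.0, 1.0)
    pos = height * (10 * s**3 - 15 * s**4 + 6 * s**5)
    vel = height / dur * (30 * s**2 - 60 * s**3 + 30 * s**4)
    acc = height / dur**2 * (60 * s - 180 * s**2 + 120 * s**3)
    return pos, vel, acc


def _one_trial(rng, pid: int, label: str, k: int, mass: float,
               t_kin: np.ndarray, fs_kin: float, fs_emg: float, n_emg: int,
               emg_gain: np.ndarray) -> TrialRecording:
    n_kin = len(t_kin)
    t_contact = rng.uniform(0.5, 0.8)
    t_lift = t_contact + rng.uniform(0.25, 0.35)
    lift_dur = rng.uniform(0.6, 0.8)

    # Grip forces: smooth raised-cosine rise from zero after contact, then a
    # plateau roughly 2.5x the object weight with a small per-hand asymmetry.
    gmax = 2.5 * mass * 9.81
    rise = 0.35
    def grip(gain):
        s = np.clip((t_kin - t_contact) / rise, 0.0, 1.0)
        return gain * gmax * 0.5 * (1.0 - np.cos(np.pi * s))
    gf_r = grip(rng.uniform(0.95, 1.05))
    gf_l = grip(rng.uniform(0.85, 0.95))

    pos, vel, acc = _min_jerk(t_kin, t_lift, lift_dur, 0.3)
    a_y = 0.02 * np.sin(2 * np.pi * 1.5 * np.clip(
        (t_kin - t_lift) / lift_dur, 0, 1))

    # EMG: burst envelope covering the grasp-and-lift, modulating white
    # noise (raw EMG is zero-mean), over a small baseline noise floor.
    t_emg = np.arange(n_emg) / fs_emg
    mid = t_lift + 0.5 * lift_dur
    env = np.exp(-0.5 * ((t_emg - mid) / 0.35) ** 2)
    emg = np.empty((len(emg_gain), n_emg))
    for c, gain in enumerate(emg_gain):
        amp = gain * (1.0 + 0.5 * mass / 0.4) * rng.uniform(0.8, 1.2)
        emg[c] = (0.005 + amp * env) * rng.standard_normal(n_emg)

    trial = TrialRecording(
        participant_id=pid, object_label=label, trial_index=k, mass=mass,
        gf_r=gf_r, gf_l=gf_l, a_z=acc, a_y=a_y, vel_z=vel, emg=emg,
        fs_kin=fs_kin, fs_emg=fs_emg)
    gf_any = np.maximum(gf_r, gf_l)
    first_contact = int(np.flatnonzero(gf_any > 0.1)[0])
    speed = np.abs(vel)
    peak = int(np.argmax(speed))
    stable = peak + 1 + int(np.flatnonzero(speed[peak + 1:] < 0.001)[0])
    trial.annotations = {
        "true_first_contact": first_contact,
        "true_stable_onset": stable,
    }
    assert n_kin == len(gf_r)
    return trial
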