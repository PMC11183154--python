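"""Configuration, file formats and the end-to-end pipeline.

A run directory produced by :func:`run_pipeline` contains:

* ``participants.csv`` — metadata table (id, age, group, pp_score, sw_score);
* ``tensor.npy`` + ``tensor.json`` — the 5-way array with its channel /
  participant index maps and preprocessing parameters;
* ``rank_sweep.csv`` — mean and SD of VAF per candidate rank;
* ``factors_{A..E}.csv`` — the scale-fixed factor matrices (mode-1 rows
  labelled with the channel names);
* ``fit_report.json`` and ``report.json`` — decomposition diagnostics and
  the inference results (classification subsets, permutation percentiles,
  regression and correlation tables, trial trends);
* ``run.log`` — per-stage structured log.

Every artifact is stamped with a hash of the configuration and the seed, so
byte-identical configurations produce identical reports.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import inference, synthdata, tensorfact
from .preprocess import (
    CHANNEL_NAMES,
    MotorTensor,
    TrialRecording,
    preprocess_dataset,
)

__all__ = [
    "PipelineConfig",
    "ConfigurationError",
    "TrialParseError",
    "run_pipeline",
    "read_trial_csv",
    "write_trial_csv",
    "write_participants_csv",
    "read_participants_csv",
    "write_factors",
    "read_factors",
    "write_tensor",
    "read_tensor",
]

logger = logging.getLogger("lifttensor")

TRIAL_COLUMNS = ["time_s", "gf_r", "gf_l", "a_z", "a_y", "vel_z"] + [
    f"emg_{i}" for i in range(1, 9)
]


class ConfigurationError(ValueError):
    pass


class TrialParseError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """All tunable parameters of the pipeline, with the analysis defaults.

    Preprocessing: 12 Hz force / 10 Hz EMG 4th-order low-pass cutoffs,
    0.1 N contact and 0.001 m/s stability thresholds, 100 ms window padding,
    500-sample time normalization with 20 trimmed per edge.  Decomposition:
    candidate ranks 1..10, 10 restarts per rank, 60% VAF threshold.
    Inference: 100 permutations, alpha = 0.05.
    """

    # paths
    data_dir: str | None = None     # read trials from here instead of simulating
    out_dir: str = "runs/latest"
    # simulation
    n_young: int = 13
    n_old: int = 16
    trials_per_object: int = 10
    fs_emg: float = 2000.0
    fs_kin: float = 200.0
    sim_rank: int = 4
    group_effect_d: float = 1.5
    trial_slope: float = -0.02
    pp_coupling: float = -0.5
    snr_db: float = 10.0
    simulate_raw: bool = True       # False: emit the tensor directly
    sim_T: int = 460                # temporal length for tensor-route simulation
    # preprocessing
    force_cutoff_hz: float = 12.0
    emg_cutoff_hz: float = 10.0
    filter_order: int = 4
    gf_threshold_n: float = 0.1
    vel_threshold_ms: float = 0.001
    pad_ms: float = 100.0
    t0: int = 500
    n_trim: int = 20
    # decomposition
    rank: int | None = None         # fixed rank; None -> use the sweep result
    R_max: int = 10
    n_realizations: int = 10
    vaf_threshold: float = 0.6
    tol: float = 1e-8
    max_iter: int = 500
    do_rank_sweep: bool = True
    # inference
    n_perm: int = 100
    alpha: float = 0.05
    exclude: list = field(default_factory=list)
    svm_c: float = 1.0
    # reproducibility
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        """Hash of the analysis parameters (paths excluded: where artifacts
        are written does not change what is computed)."""
        payload = {k: v for k, v in self.to_dict().items()
                   if k not in ("out_dir", "data_dir")}
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Trial and table I/O
# ---------------------------------------------------------------------------

def write_trial_csv(trial: TrialRecording, path) -> None:
    """One delimited text file per trial, on the EMG time base.

    Kinematic columns (sampled at ``fs_kin``) are step-repeated to the EMG
    rate so a single rectangular table holds both; metadata travel in
    ``#``-prefixed header lines.
    """
    ratio = int(round(trial.fs_emg / trial.fs_kin))
    n_emg = trial.emg.shape[1]
    rep = lambda x: np.repeat(np.asarray(x), ratio)[:n_emg]  # noqa: E731
    df = pd.DataFrame({
        "time_s": np.arange(n_emg) / trial.fs_emg,
        "gf_r": rep(trial.gf_r), "gf_l": rep(trial.gf_l),
        "a_z": rep(trial.a_z), "a_y": rep(trial.a_y),
        "vel_z": rep(trial.vel_z),
        **{f"emg_{i + 1}": trial.emg[i] for i in range(trial.emg.shape[0])},
    })
    header = [
        f"# participant_id={trial.participant_id}",
        f"# object_label={trial.object_label}",
        f"# trial_index={trial.trial_index}",
        f"# mass={trial.mass}",
        f"# fs_kin={trial.fs_kin}",
        f"# fs_emg={trial.fs_emg}",
    ]
    for key, value in trial.annotations.items():
        header.append(f"# {key}={value}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("\n".join(header) + "\n")
        df.to_csv(fh, index=False, float_format="%.9g")


def read_trial_csv(path) -> TrialRecording:
    """Parse a trial file written by :func:`write_trial_csv`."""
    meta: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith("#"):
                break
            try:
                key, value = line[1:].strip().split("=", 1)
            except ValueError as exc:
                raise TrialParseError(
                    f"{path}:{lineno}: malformed metadata line") from exc
            meta[key.strip()] = value.strip()
    df = pd.read_csv(path, comment="#")
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise TrialParseError(f"{path}: missing column(s) {missing}")
    if df[TRIAL_COLUMNS].isna().any().any():
        bad = int(np.argmax(df[TRIAL_COLUMNS].isna().any(axis=1).values))
        raise TrialParseError(f"{path}: NaN cell near data row {bad + 1}")
    try:
        fs_kin = float(meta["fs_kin"])
        fs_emg = float(meta["fs_emg"])
        trial = TrialRecording(
            participant_id=int(meta["participant_id"]),
            object_label=meta["object_label"],
            trial_index=int(meta["trial_index"]),
            mass=float(meta["mass"]),
            gf_r=df["gf_r"].values[:: int(round(fs_emg / fs_kin))],
            gf_l=df["gf_l"].values[:: int(round(fs_emg / fs_kin))],
            a_z=df["a_z"].values[:: int(round(fs_emg / fs_kin))],
            a_y=df["a_y"].values[:: int(round(fs_emg / fs_kin))],
            vel_z=df["vel_z"].values[:: int(round(fs_emg / fs_kin))],
            emg=df[[f"emg_{i}" for i in range(1, 9)]].values.T,
            fs_kin=fs_kin, fs_emg=fs_emg,
        )
    except KeyError as exc:
        raise TrialParseError(f"{path}: missing metadata {exc}") from exc
    for key in ("true_first_contact", "true_stable_onset"):
        if key in meta:
            trial.annotations[key] = int(meta[key])
    return trial


def write_participants_csv(metas, path) -> None:
    pd.DataFrame([asdict(m) for m in metas]).to_csv(path, index=False)


def read_participants_csv(path) -> list[synthdata.ParticipantMeta]:
    df = pd.read_csv(path)
    return [
        synthdata.ParticipantMeta(
            participant_id=int(row.participant_id), age=float(row.age),
            group=str(row.group), pp_score=float(row.pp_score),
            sw_score=float(row.sw_score))
        for row in df.itertuples()
    ]


def write_tensor(mt: MotorTensor, stem) -> None:
    """Array as .npy plus a JSON sidecar with the index maps."""
    stem = Path(stem)
    np.save(stem.with_suffix(".npy"), mt.X)
    sidecar = {
        "dims": ["channel", "time", "object", "participant", "trial"],
        "shape": list(mt.X.shape),
        "channel_names": list(mt.channel_names),
        "participant_ids": list(mt.participant_ids),
        "object_labels": list(mt.object_labels),
        "attrs": {k: _jsonable(v) for k, v in mt.attrs.items()},
    }
    stem.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_tensor(stem) -> MotorTensor:
    stem = Path(stem)
    X = np.load(stem.with_suffix(".npy"))
    sidecar = json.loads(stem.with_suffix(".json").read_text())
    return MotorTensor(
        X, channel_names=tuple(sidecar["channel_names"]),
        participant_ids=tuple(sidecar["participant_ids"]),
        object_labels=tuple(sidecar["object_labels"]),
        attrs=sidecar.get("attrs", {}))


_FACTOR_FILES = ("A", "B", "C", "D", "E")


def write_factors(model: tensorfact.FactorModel, out_dir,
                  channel_names=CHANNEL_NAMES, participant_ids=None) -> None:
    """Five CSV tables, one per mode; mode-1 rows carry the channel labels."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cols = [f"component_{r + 1}" for r in range(model.rank)]
    labels = [
        list(channel_names) if len(channel_names) == model.shape[0]
        else list(range(1, model.shape[0] + 1)),
        list(range(1, model.shape[1] + 1)),
        ["heavy", "light"] if model.shape[2] == 2
        else list(range(1, model.shape[2] + 1)),
        list(participant_ids) if participant_ids
        else list(range(1, model.shape[3] + 1)),
        list(range(1, model.shape[4] + 1)),
    ]
    names = ("channel", "time", "object", "participant", "trial")
    for tag, F, lab, idx_name in zip(_FACTOR_FILES, model.factors, labels, names):
        df = pd.DataFrame(F, columns=cols, index=pd.Index(lab, name=idx_name))
        df.to_csv(out_dir / f"factors_{tag}.csv")


def read_factors(out_dir) -> tensorfact.FactorModel:
    out_dir = Path(out_dir)
    factors = []
    for tag in _FACTOR_FILES:
        df = pd.read_csv(out_dir / f"factors_{tag}.csv", index_col=0)
        factors.append(df.values)
    return tensorfact.FactorModel(tuple(factors))


def _jsonable(v):
    if isinstance(v, (np.floating, np.integer)):
        return v.item()
    if isinstance(v, float) and np.isinf(v):
        return "inf"
    return v


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig) -> Path:
    """Execute simulate -> preprocess -> decompose -> rank sweep -> infer.

    Returns the run directory.  With ``data_dir`` set, trials are read from
    CSV files there instead of being simulated.  Reruns with an identical
    configuration reproduce identical artifacts.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out / "run.log")
    chash = config.config_hash()
    logger.info("run start | config_hash=%s seed=%d", chash, config.seed)
    (out / "config.yaml").write_text(yaml.safe_dump(config.to_dict()))

    mt, metas = _stage_data(config)
    write_participants_csv(metas, out / "participants.csv")
    mt.attrs["config_hash"] = chash
    mt.attrs["seed"] = config.seed
    write_tensor(mt, out / "tensor")
    logger.info("tensor assembled | shape=%s", mt.X.shape)

    sweep = None
    rank = config.rank
    if config.do_rank_sweep:
        sweep = tensorfact.select_rank(
            mt.X, R_max=config.R_max, n_realizations=config.n_realizations,
            threshold=config.vaf_threshold, seed=config.seed,
            tol=config.tol, max_iter=config.max_iter)
        pd.DataFrame({
            "rank": sweep.candidate_ranks, "mean_vaf": sweep.mean_vaf,
            "sd_vaf": sweep.sd_vaf,
        }).to_csv(out / "rank_sweep.csv", index=False)
        if rank is None:
            rank = sweep.selected_rank
        logger.info("rank sweep done | selected_R=%d", sweep.selected_rank)
    if rank is None:
        raise ConfigurationError("no rank given and rank sweep disabled")

    model, fit = tensorfact.ncp_best_of(
        mt.X, rank, n_restarts=config.n_realizations, seed=config.seed,
        tol=config.tol, max_iter=config.max_iter)
    model = tensorfact.fix_scale(model)
    # deterministic component order: by object-factor column magnitude
    order = np.argsort(-np.linalg.norm(model.C, axis=0), kind="stable")
    model = tensorfact.FactorModel(tuple(f[:, order] for f in model.factors))
    write_factors(model, out, channel_names=mt.channel_names,
                  participant_ids=list(mt.participant_ids))
    (out / "fit_report.json").write_text(json.dumps({
        "objective": fit.objective, "mse": fit.mse, "vaf": fit.vaf,
        "n_iter": fit.n_iter, "seed": fit.seed, "converged": fit.converged,
        "rank": rank, "config_hash": chash,
    }, indent=1))
    logger.info("decomposition done | rank=%d vaf=%.4f", rank, fit.vaf)

    report = _stage_inference(config, model, metas)
    report["config_hash"] = chash
    report["seed"] = config.seed
    report["rank"] = rank
    if sweep is not None:
        report["selected_rank"] = sweep.selected_rank
    (out / "report.json").write_text(json.dumps(report, indent=1))
    logger.info("run complete | %s", out)
    return out


def _stage_data(config: PipelineConfig):
    if config.data_dir is not None:
        data_dir = Path(config.data_dir)
        if not data_dir.is_dir():
            raise ConfigurationError(f"input directory {data_dir} not found")
        metas = read_participants_csv(data_dir / "participants.csv")
        trials = [read_trial_csv(p) for p in sorted(data_dir.glob("trial_*.csv"))]
        if not trials:
            raise ConfigurationError(f"no trial_*.csv files in {data_dir}")
        mt = _preprocess(config, trials, metas)
        return mt, metas
    # simulate
    if config.simulate_raw:
        metas = synthdata.generate_participants(
            config.n_young, config.n_old, config.pp_coupling,
            seed=config.seed)
        trials = synthdata.generate_raw_trials(
            metas, trials_per_object=config.trials_per_object,
            fs_emg=config.fs_emg, fs_kin=config.fs_kin, seed=config.seed)
        mt = _preprocess(config, trials, metas)
        return mt, metas
    P = config.n_young + config.n_old
    truth = synthdata.generate_planted_model(
        (12, config.sim_T, 2, P, config.trials_per_object),
        config.sim_rank, group_effect_d=config.group_effect_d,
        trial_slope=config.trial_slope, seed=config.seed,
        n_young=config.n_young, pp_coupling=config.pp_coupling,
        snr_db=config.snr_db)
    return synthdata.generate_tensor_dataset(truth, seed=config.seed)


def _preprocess(config: PipelineConfig, trials, metas) -> MotorTensor:
    return preprocess_dataset(
        trials, metas, force_cutoff=config.force_cutoff_hz,
        emg_cutoff=config.emg_cutoff_hz, filter_order=config.filter_order,
        gf_threshold=config.gf_threshold_n,
        vel_threshold=config.vel_threshold_ms, pad_ms=config.pad_ms,
        t0=config.t0, n_trim=config.n_trim)


def _stage_inference(config: PipelineConfig, model, metas) -> dict:
    D = model.D
    E = model.E
    R = model.rank
    groups = [m.group for m in metas]
    ages = np.array([m.age for m in metas])
    pp = np.array([m.pp_score for m in metas])

    results = inference.subset_search(D, groups, C=config.svm_c)
    best = results[0]
    classification = {
        "best_subset": [r + 1 for r in best.factor_subset],
        "best_auc": best.auc, "best_acc": best.acc,
        "subsets": [
            {"subset": [r + 1 for r in res.factor_subset],
             "auc": res.auc, "acc": res.acc}
            for res in results
        ],
    }
    permutation = {}
    for r in best.factor_subset:
        pr = inference.permutation_importance(
            D, groups, best.factor_subset, r, n_perm=config.n_perm,
            seed=config.seed, C=config.svm_c)
        permutation[str(r + 1)] = {
            "percentile_auc": pr.percentile_auc,
            "percentile_acc": pr.percentile_acc,
        }

    regression = {}
    for name, y in (("age", ages), ("pp", pp)):
        reg = inference.fit_regression(D, y)
        regression[name] = {
            "b0": reg.b0, "b": reg.b.tolist(),
            "p_values": reg.p_values.tolist(),
            "p_intercept": reg.p_intercept, "r_squared": reg.r_squared,
        }

    correlation = {}
    for name, y in (("age", ages), ("pp", pp)):
        correlation[name] = {}
        for r in range(R):
            corr = inference.correlate(
                D[:, r], y, exclude=config.exclude, alpha=config.alpha,
                n_comparisons=R)
            correlation[name][str(r + 1)] = {
                "rho": corr.rho, "p": corr.p,
                "significant": corr.significant, "n_used": corr.n_used,
            }

    trends = {}
    for r in range(R):
        tr = inference.mann_kendall(E[:, r], alpha=config.alpha)
        trends[str(r + 1)] = {
            "S": tr.S, "z": tr.z, "p": tr.p, "direction": tr.direction,
            "ols_slope": tr.ols_slope,
        }

    group_tests = {}
    for r in range(R):
        t, p, sig = inference.group_difference_test(
            D[:, r], groups, n_comparisons=R, alpha=config.alpha)
        group_tests[str(r + 1)] = {"t": t, "p": p, "significant": sig}

    return {
        "classification": classification,
        "permutation_importance": permutation,
        "regression": regression,
        "correlation": correlation,
        "trial_trends": trends,
        "group_difference": group_tests,
    }


def _setup_logging(logfile) -> None:
    logger.setLevel(logging.INFO)
    for h in list(logger.handlers):
        logger.removeHandler(h)
    handler = logging.FileHandler(logfile, mode="w")
    handler.setFormatter(logging.Formatter(
        "%(asctime)s | %(levelname)s | %(message)s"))
    logger.addHandler(handler)
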