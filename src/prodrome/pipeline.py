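"""End-to-end experiment orchestration.

simulate -> featurize -> impute -> split -> train -> score -> evaluate ->
posthoc, as one seeded, manifest-recorded sweep over (architecture, hidden
units, percent of relapse-participant healthy days in training).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from itertools import product
from pathlib import Path

import numpy as np
import pandas as pd

from . import detectors, evaluation, posthoc, scoring, splits as splits_mod
from .features import extract_hourly_features
from .impute import fill_type2
from .schema import FEATURES, LABEL_NR30
from .synthetic_cohort import CohortConfig, generate_cohort

logger = logging.getLogger(__name__)

FEATURE_COLS = list(FEATURES)


@dataclass
class ExperimentConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    archs: tuple = ("fnn_ad",)
    hidden_grid: tuple = (20,)
    pct_grid: tuple = (80,)
    mc_iterations: int = 100
    block_len_days: int = 5
    base_seed: int = 0
    train_kwargs: dict = field(default_factory=dict)


@dataclass
class ConfigResult:
    config: str
    records: pd.DataFrame        # iteration, participant_id, sensitivity, specificity, ratio
    summary: dict
    flags: pd.DataFrame          # accumulated N_T daily flags across iterations
    taus: pd.DataFrame
    model: object = None


@dataclass
class ExperimentResult:
    configs: dict                # name -> ConfigResult
    ranking: pd.DataFrame | None
    best: str
    timeline: pd.DataFrame
    posthoc_reports: dict
    mannwhitney: tuple | None
    imputed: object
    calendars: dict
    ground_truth: dict


def day_label_frame(calendars: dict) -> pd.Series:
    """MultiIndex (participant_id, date) -> label for all participants."""
    parts = []
    for pid, cal in sorted(calendars.items()):
        lab = cal.day_labels
        parts.append(
            pd.Series(
                lab.to_numpy(),
                index=pd.MultiIndex.from_product([[pid], lab.index], names=["participant_id", "date"]),
            )
        )
    return pd.concat(parts)


def _block_segments(values: pd.DataFrame, blocks: list) -> list:
    """One (block, hour-matrix, dates) triple per block, rows in time order."""
    idx = pd.MultiIndex.from_frame(values[["participant_id", "date"]])
    out = []
    for b in blocks:
        keys = {(b.participant_id, d) for d in b.dates}
        sub = values[idx.isin(keys)]
        out.append((b, sub))
    return out


def _hour_matrix(sub: pd.DataFrame) -> np.ndarray:
    return sub[FEATURE_COLS].to_numpy(float)


def _hourly_scores_for_blocks(model, block_subs, dist=None):
    """Per-hour anomaly scores for every fully-predicted hour of each block.

    Returns a DataFrame (participant_id, date, score).  If ``dist`` is None,
    returns instead the stacked error vectors (to fit the distribution).
    """
    err_frames = []
    score_frames = []
    for b, sub in block_subs:
        X = _hour_matrix(sub)
        if len(X) == 0:
            continue
        if model.arch == "fnn_ad":
            Xs, R = detectors.reconstruct(model, X)
            idx = np.arange(len(X))
            E = scoring.reconstruction_errors(Xs, R)
        elif model.arch == "gru_seq2seq":
            Xs, WR = detectors.reconstruct(model, X)
            idx, R = scoring.consolidate_hour_predictions(WR, model.window)
            if len(idx) == 0:
                continue
            E = scoring.reconstruction_errors(Xs[idx], R)
        elif model.arch == "lof":
            E = detectors.reconstruct(model, X)
            idx = np.arange(len(X))
        else:
            raise ValueError(model.arch)
        if dist is None:
            err_frames.append(E)
        else:
            s = scoring.mahalanobis_score(E, dist)
            score_frames.append(
                pd.DataFrame(
                    {
                        "participant_id": sub["participant_id"].to_numpy()[idx],
                        "date": sub["date"].to_numpy()[idx],
                        "score": np.atleast_1d(s),
                    }
                )
            )
    if dist is None:
        return np.concatenate(err_frames) if err_frames else np.empty((0, len(FEATURE_COLS)))
    if not score_frames:
        return pd.DataFrame(columns=["participant_id", "date", "score"])
    return pd.concat(score_frames, ignore_index=True)


@dataclass
class TrainedConfig:
    """Everything the scoring stage needs: the trained model(s), the block
    assignment and the pooled daily scores over the mixed pool."""

    name: str
    arch: str
    hidden: int
    pct: int
    base_seed: int
    block_len_days: int
    models: dict
    splits: object
    daily_pool: pd.DataFrame
    day_block: dict


def train_config(
    values: pd.DataFrame,
    calendars: dict,
    arch: str,
    hidden: int,
    pct: int,
    base_seed: int,
    block_len_days: int = 5,
    train_kwargs: dict | None = None,
) -> TrainedConfig:
    """Split, train one (arch, hidden, pct) configuration and precompute the
    daily anomaly scores for the mixed pool."""
    train_kwargs = dict(train_kwargs or {})
    name = f"{arch}:h{hidden}:p{pct}"
    relapse_pids = {pid for pid, cal in calendars.items() if cal.relapse_dates}
    labels = day_label_frame(calendars)

    all_blocks = []
    for pid, cal in sorted(calendars.items()):
        all_blocks.extend(splits_mod.blocks_for_participant(pid, cal.day_labels, block_len_days))
    sp = splits_mod.assign_splits(all_blocks, pct, base_seed, relapse_pids, block_len_days)

    hr_subs = _block_segments(values, sp.h_r)
    hcv_subs = _block_segments(values, sp.h_cv)
    np_subs = _block_segments(values, sp.n_pool)

    h_r = np.concatenate([_hour_matrix(s) for _, s in hr_subs]) if hr_subs else np.empty((0, len(FEATURE_COLS)))
    h_cv = np.concatenate([_hour_matrix(s) for _, s in hcv_subs]) if hcv_subs else np.empty((0, len(FEATURE_COLS)))

    if arch == "fnn_ad":
        model = detectors.train_fnn_ad(h_r, h_cv, hidden, seed=base_seed, **train_kwargs)
        models = {None: model}
    elif arch == "gru_seq2seq":
        model = detectors.train_gru_seq2seq(
            [_hour_matrix(s) for _, s in hr_subs],
            [_hour_matrix(s) for _, s in hcv_subs],
            hidden,
            seed=base_seed,
            **train_kwargs,
        )
        models = {None: model}
    elif arch == "lof":
        models = {}
        for pid in sorted(relapse_pids):
            hr_p = np.concatenate(
                [_hour_matrix(s) for b, s in hr_subs if b.participant_id == pid] or [np.empty((0, len(FEATURE_COLS)))]
            )
            hcv_p = np.concatenate(
                [_hour_matrix(s) for b, s in hcv_subs if b.participant_id == pid] or [np.empty((0, len(FEATURE_COLS)))]
            )
            if len(hr_p) < 12 or len(hcv_p) == 0:
                logger.warning("%s: too little healthy data for LOF; skipped", pid)
                continue
            models[pid] = detectors.train_lof(hr_p, hcv_p, seed=base_seed, **train_kwargs)
        model = models
    else:
        raise ValueError(f"unknown architecture {arch!r}")

    # expected-error distribution from the healthy validation set
    daily_pool_parts = []
    for pid_key, mdl in models.items():
        if pid_key is None:
            hcv_for, np_for = hcv_subs, np_subs
        else:
            hcv_for = [(b, s) for b, s in hcv_subs if b.participant_id == pid_key]
            np_for = [(b, s) for b, s in np_subs if b.participant_id == pid_key]
        E_cv = _hourly_scores_for_blocks(mdl, hcv_for, dist=None)
        if len(E_cv) < 2:
            continue
        dist = scoring.fit_error_distribution(E_cv)
        hourly = _hourly_scores_for_blocks(mdl, np_for, dist=dist)
        if len(hourly):
            daily_pool_parts.append(scoring.daily_scores(hourly))
    daily_pool = (
        pd.concat(daily_pool_parts, ignore_index=True)
        if daily_pool_parts
        else pd.DataFrame(columns=["participant_id", "date", "s_d", "n_hours"])
    )
    key = pd.MultiIndex.from_frame(daily_pool[["participant_id", "date"]])
    daily_pool["label"] = labels.reindex(key).to_numpy()

    # block membership map for MC partitioning of daily scores
    day_block = {}
    for b in sp.n_pool:
        for d in b.dates:
            day_block[(b.participant_id, d)] = b.key()

    return TrainedConfig(
        name=name, arch=arch, hidden=hidden, pct=pct, base_seed=base_seed,
        block_len_days=block_len_days, models=models, splits=sp,
        daily_pool=daily_pool, day_block=day_block,
    )


def score_config(trained: TrainedConfig, mc_iterations: int) -> ConfigResult:
    """Monte Carlo threshold/evaluation loop over a trained configuration."""
    sp = trained.splits
    daily_pool = trained.daily_pool
    day_block = trained.day_block
    base_seed = trained.base_seed

    records, flags_parts, taus_parts = [], [], []
    for it in range(1, mc_iterations + 1):
        n_cv, n_t = splits_mod.monte_carlo_partition(sp.n_pool, it, base_seed)
        cv_keys = {b.key() for b in n_cv}
        in_cv = np.array([day_block[k] in cv_keys for k in zip(daily_pool["participant_id"], daily_pool["date"])])
        d_cv = daily_pool[in_cv]
        d_t = daily_pool[~in_cv]
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("ignore")
            taus = scoring.learn_threshold(d_cv)
        if taus.empty:
            continue
        flagged = scoring.flag_anomalies(d_t, taus)
        taus["iteration"] = it
        taus_parts.append(taus)
        flagged["iteration"] = it
        flags_parts.append(flagged)
        for pid, sub in flagged.groupby("participant_id", sort=True):
            lab = sub["label"].to_numpy()
            if not (lab == LABEL_NR30).any():
                continue
            m = evaluation.confusion_metrics(sub["flag"].to_numpy(), lab)
            n_drh = int((lab == "DRH").sum())
            floor = 1.0 / (n_drh + 1)
            ratio = m["tpr"] / max(m["fpr"] if np.isfinite(m["fpr"]) else floor, floor)
            records.append(
                {
                    "iteration": it,
                    "participant_id": pid,
                    "sensitivity": m["sensitivity"],
                    "specificity": m["specificity"],
                    "ratio": ratio,
                }
            )

    records = pd.DataFrame(records, columns=["iteration", "participant_id", "sensitivity", "specificity", "ratio"])
    summary = (
        evaluation.aggregate_monte_carlo(records)
        if len(records)
        else {"sensitivity": {"median": np.nan}, "specificity": {"median": np.nan}}
    )
    flags = pd.concat(flags_parts, ignore_index=True) if flags_parts else pd.DataFrame(
        columns=["participant_id", "date", "s_d", "n_hours", "label", "tau", "flag", "iteration"]
    )
    taus_all = pd.concat(taus_parts, ignore_index=True) if taus_parts else pd.DataFrame()
    return ConfigResult(trained.name, records, summary, flags, taus_all, trained.models)


def run_single_config(
    values: pd.DataFrame,
    calendars: dict,
    arch: str,
    hidden: int,
    pct: int,
    mc_iterations: int,
    base_seed: int,
    block_len_days: int = 5,
    train_kwargs: dict | None = None,
) -> ConfigResult:
    """Train one configuration and run the Monte Carlo evaluation loop."""
    trained = train_config(
        values, calendars, arch, hidden, pct, base_seed, block_len_days, train_kwargs
    )
    return score_config(trained, mc_iterations)


def run_experiment(cfg: ExperimentConfig, out_dir: str | Path | None = None) -> ExperimentResult:
    """Execute the full sweep and post hoc analyses; optionally write results."""
    events, calendars, ground_truth = generate_cohort(cfg.cohort)
    fm = extract_hourly_features(events, calendars)
    labels = day_label_frame(calendars)
    imputed = fill_type2(fm, day_labels=labels)
    values = imputed.values

    configs = {}
    for arch, hidden, pct in product(cfg.archs, cfg.hidden_grid, cfg.pct_grid):
        res = run_single_config(
            values, calendars, arch, hidden, pct,
            cfg.mc_iterations, cfg.base_seed, cfg.block_len_days, cfg.train_kwargs,
        )
        configs[res.config] = res
        logger.info("config %s: %s", res.config, res.summary)

    ranking = None
    if len(configs) >= 2:
        ratio_rows = []
        for name, res in configs.items():
            if res.records.empty:
                continue
            med = res.records.groupby("participant_id")["ratio"].median()
            for pid, r in med.items():
                ratio_rows.append({"config": name, "participant_id": pid, "ratio": r})
        if ratio_rows:
            ranking = evaluation.rank_models(pd.DataFrame(ratio_rows))
    best = ranking["config"].iloc[0] if ranking is not None else next(iter(configs))
    best_res = configs[best]

    relapse_dates = {pid: cal.relapse_dates for pid, cal in calendars.items() if cal.relapse_dates}
    timeline = (
        evaluation.anomaly_rate_timeline(best_res.flags, relapse_dates)
        if len(best_res.flags)
        else pd.DataFrame()
    )

    # post hoc on multirelapse participants (falls back to all relapsers)
    type2_by_day = (
        pd.DataFrame(
            {
                "participant_id": values["participant_id"],
                "date": values["date"],
                "t2": imputed.type2_flag.to_numpy(),
            }
        )
        .groupby(["participant_id", "date"], sort=True)["t2"]
        .sum()
    )
    reports = {}
    mw = None
    if len(best_res.flags):
        flags = best_res.flags
        multi = [pid for pid, rd in relapse_dates.items() if len(rd) > 1] or sorted(relapse_dates)
        for pid in multi:
            sub = flags[(flags["participant_id"] == pid) & flags["flag"]]
            flagged_days = set(sub.loc[sub["label"] == LABEL_NR30, "date"])
            hourly = values[values["participant_id"] == pid]
            import warnings as _w

            with _w.catch_warnings():
                _w.simplefilter("ignore")
                rep = posthoc.feature_effect_ranking(
                    pid, hourly, flagged_days, calendars[pid].day_labels
                )
                day_flags = flags[flags["participant_id"] == pid].groupby("date")["flag"].max()
                nr30_anom = day_flags.index.isin(flagged_days) & day_flags.to_numpy()
                t2_days = (
                    type2_by_day.loc[pid].reindex(day_flags.index).fillna(0).to_numpy() > 0
                )
                try:
                    rep.missingness_or = posthoc.missingness_odds_ratio(t2_days, nr30_anom)
                except ValueError:
                    pass
            reports[pid] = rep

        per_day = flags.groupby(["participant_id", "date"], sort=True)["flag"].max()
        t2_counts = type2_by_day.reindex(per_day.index).fillna(0).to_numpy()
        anom = per_day.to_numpy()
        if anom.any() and (~anom).any():
            mw = posthoc.mannwhitney_type2(t2_counts[anom], t2_counts[~anom])

    result = ExperimentResult(
        configs=configs, ranking=ranking, best=best, timeline=timeline,
        posthoc_reports=reports, mannwhitney=mw, imputed=imputed,
        calendars=calendars, ground_truth=ground_truth,
    )
    if out_dir is not None:
        _write_results(result, cfg, Path(out_dir))
    return result


def _write_results(result: ExperimentResult, cfg: ExperimentConfig, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for name, res in result.configs.items():
        s, p = res.summary["sensitivity"], res.summary["specificity"]
        rows.append(
            {
                "config": name,
                "sensitivity_median": s.get("median"),
                "sensitivity_q1": s.get("q1"),
                "sensitivity_q3": s.get("q3"),
                "specificity_median": p.get("median"),
                "specificity_q1": p.get("q1"),
                "specificity_q3": p.get("q3"),
            }
        )
    pd.DataFrame(rows).to_csv(out / "summary.csv", index=False)
    if result.ranking is not None:
        result.ranking.to_csv(out / "ranking.csv", index=False)
    if len(result.timeline):
        result.timeline.to_csv(out / "timeline.csv", index=False)
    for name, res in result.configs.items():
        res.records.to_csv(out / f"records_{name.replace(':', '_')}.csv", index=False)
    ph = {
        pid: {
            "top5": rep.top5,
            "missingness_or": rep.missingness_or,
            "effects": rep.effects.to_dict("records"),
        }
        for pid, rep in result.posthoc_reports.items()
    }
    manifest = {
        "base_seed": cfg.base_seed,
        "mc_iterations": cfg.mc_iterations,
        "block_len_days": cfg.block_len_days,
        "archs": list(cfg.archs),
        "hidden_grid": list(cfg.hidden_grid),
        "pct_grid": list(cfg.pct_grid),
        "cohort": {k: str(v) for k, v in asdict(cfg.cohort).items()},
        "best": result.best,
    }
    with open(out / "posthoc.json", "w") as fh:
        json.dump(ph, fh, indent=2, default=float)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    if result.mannwhitney is not None:
        with open(out / "mannwhitney.json", "w") as fh:
            json.dump({"U": result.mannwhitney[0], "p": result.mannwhitney[1]}, fh)
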