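"""End-to-end orchestration of the analysis on a synthetic cohort.

``run_cohort`` composes the stages in experiment order: simulate cohort ->
stratify -> cross-validated accuracy + peak time -> exclusions -> final
decoders -> decode retrieval epochs -> sequenceness (TDLM with permutation
thresholds, mean-lag test, performance correlation) -> clustered-reactivation
analyses (differential time course with permutation test, distance profile
with rm-ANOVA, optional pre/post comparison).  All outputs are written as TSV
summaries plus an HDF5 results store and a JSON run manifest; ``report``
regenerates the TSVs from the store without recomputation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from . import decoding, reactivation, tdlm
from .synthetic_data import SimulationConfig, simulate_cohort
from .task_graph import build_task_graph

__all__ = ["RunConfig", "CohortResult", "run_cohort", "report"]

log = logging.getLogger("graphreplay")


@dataclass
class RunConfig:
    """Serializable configuration of a full pipeline run."""

    sim: SimulationConfig = field(default_factory=SimulationConfig)
    t_train: float = 0.21
    penalty_C: float = 6.0
    null_ratio: float = 2.0
    cv_folds: int = 5
    max_lag_ms: float = 250.0
    n_perm: int = 1000
    smoothing_sigma: float = 1.0
    alpha: float = 0.05
    n_shuffles: int = 10000
    window: tuple = (0.22, 0.26)
    permutation_mode: str = "rows"
    out_dir: str = "graphreplay_out"
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.sim, dict):
            self.sim = SimulationConfig(**self.sim)
        self.window = tuple(self.window)
        self.sim.seed = int(self.seed)

    def to_yaml(self) -> str:
        return yaml.safe_dump(_to_plain(dataclasses.asdict(self)), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        obj = yaml.safe_load(text)
        if not isinstance(obj, dict):
            raise ValueError("config must be a YAML mapping")
        return cls(**obj)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def _to_plain(obj):
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


@dataclass
class CohortResult:
    """Bundle of pipeline outputs for one simulated cohort."""

    config: RunConfig
    included: np.ndarray
    peak_accuracy: np.ndarray
    peak_time: np.ndarray
    retrieval_accuracy: np.ndarray
    accuracy_curves: np.ndarray
    sequenceness: tdlm.SequencenessResult
    performance_r: float
    performance_p: float
    differential: np.ndarray
    differential_p: np.ndarray
    significant_times: np.ndarray
    peak_reactivation_time: float
    profile: reactivation.ReactivationProfile
    pre_post: tuple | None


class StageError(RuntimeError):
    def __init__(self, stage: str, participant, err: Exception):
        super().__init__(f"stage {stage!r}"
                         + (f" (participant {participant})" if participant is not None else "")
                         + f" failed: {err}")
        self.stage = stage
        self.participant = participant


def run_cohort(cfg: RunConfig) -> CohortResult:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    timings = {}
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xA11A]))

    def stage(name, fn, participant=None):
        t0 = time.time()
        try:
            res = fn()
        except Exception as err:  # noqa: BLE001 - abort with stage context
            raise StageError(name, participant, err) from err
        timings[name] = timings.get(name, 0.0) + time.time() - t0
        log.info("stage %-24s %6.1f s", name, time.time() - t0)
        return res

    graph = stage("build_graph", lambda: build_task_graph())
    graph_json = graph.to_json()
    g, cohort = stage("simulate_cohort", lambda: simulate_cohort(cfg.sim, graph))

    peak_acc, peak_t, curves = [], [], []
    for part in cohort:
        def cv(part=part):
            loc = decoding.stratify_trials(part.localizer, rng)
            return decoding.crossval_accuracy_timecourse(
                loc, C=cfg.penalty_C, n_folds=cfg.cv_folds, rng=rng)
        acc, pt, pa = stage("crossval", cv, part.participant)
        curves.append(acc)
        peak_t.append(pt)
        peak_acc.append(pa)
    peak_acc = np.array(peak_acc)
    peak_t = np.array(peak_t)
    curves = np.stack(curves)

    retrieval_acc = np.array([p.retrieval.meta["correct"].mean() for p in cohort])
    included = decoding.apply_exclusion_criteria(peak_acc, retrieval_acc)
    for p, ok in enumerate(included):
        if not ok:
            reason = ("peak accuracy < 30%" if peak_acc[p] < 0.30
                      else "retrieval performance < 50%")
            log.info("participant %d excluded: %s", p, reason)
    if not included.any():
        raise StageError("exclusions", None,
                         RuntimeError("no participant passed inclusion"))

    kept = [p for p, ok in zip(cohort, included) if ok]
    prob_list, meta_list, learn_probs, learn_meta = [], [], [], []
    for part in kept:
        def decode(part=part):
            dec = decoding.train_final_decoders(
                part.localizer, t_train=cfg.t_train, C=cfg.penalty_C,
                null_ratio=cfg.null_ratio, rng=rng)
            probs = decoding.apply_decoders(dec, part.retrieval)
            lp = (decoding.apply_decoders(dec, part.learning)
                  if part.learning is not None else None)
            return probs, lp
        probs, lp = stage("decode", decode, part.participant)
        prob_list.append(probs)
        meta_list.append(part.retrieval.meta)
        if lp is not None:
            learn_probs.append(lp)
            learn_meta.append(part.learning.meta)

    tmats = tdlm.build_transition_matrices(graph)
    seq = stage("sequenceness", lambda: tdlm.sequenceness_analysis(
        prob_list, tmats, max_lag_ms=cfg.max_lag_ms, n_perm=cfg.n_perm,
        rng=rng, mode=cfg.permutation_mode))
    mean_seq = seq.zf.mean(axis=1)
    if len(kept) >= 3 and np.std(retrieval_acc[included]) > 0:
        perf_r, perf_p = tdlm.correlate_with_performance(
            mean_seq, retrieval_acc[included])
    else:
        perf_r, perf_p = float("nan"), float("nan")

    smoothed = [reactivation.smooth_probabilities(p, cfg.smoothing_sigma)
                for p in prob_list]
    diff, diff_p, sig = stage("reactivation", lambda: (
        reactivation.reactivation_permutation_test(
            smoothed, graph, meta_list, n_shuffles=cfg.n_shuffles,
            alpha=cfg.alpha, rng=rng)))
    peak_time = stage("peak_time", lambda: reactivation.global_peak_time(
        smoothed, meta_list))
    profile = stage("distance_profile", lambda: reactivation.distance_profile(
        smoothed, graph, meta_list, peak_time))

    pre_post = None
    if learn_probs:
        smoothed_learn = [reactivation.smooth_probabilities(p, cfg.smoothing_sigma)
                          for p in learn_probs]
        pre_post = stage("pre_post", lambda: reactivation.pre_post_comparison(
            smoothed_learn, smoothed, graph, learn_meta, meta_list,
            window=cfg.window))

    result = CohortResult(
        config=cfg, included=included, peak_accuracy=peak_acc,
        peak_time=peak_t, retrieval_accuracy=retrieval_acc,
        accuracy_curves=curves, sequenceness=seq,
        performance_r=perf_r, performance_p=perf_p,
        differential=diff, differential_p=diff_p, significant_times=sig,
        peak_reactivation_time=peak_time, profile=profile, pre_post=pre_post)

    _write_store(out, result, graph_json, cohort[0].localizer.times,
                 prob_list[0].times)
    _write_tsvs(out, result, prob_list[0].times, cohort[0].localizer.times)
    from . import __version__ as pkg_version

    manifest = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "package_version": pkg_version,
        "versions": _lib_versions(),
        "elapsed_s": round(time.time() - t_start, 2),
        "timings_s": {k: round(v, 2) for k, v in timings.items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    (out / "config.yaml").write_text(cfg.to_yaml())
    (out / "run.log").write_text("\n".join(
        f"{k}\t{v:.2f}s" for k, v in timings.items()) + "\n")
    return result


def _lib_versions() -> dict:
    import scipy
    import sklearn

    return {"numpy": np.__version__, "scipy": scipy.__version__,
            "sklearn": sklearn.__version__, "pandas": pd.__version__}


def _write_store(out: Path, r: CohortResult, graph_json: str,
                 loc_times, ret_times) -> None:
    with h5py.File(out / "results.h5", "w") as f:
        f.attrs["graph_json"] = graph_json
        f.create_dataset("loc_times", data=np.asarray(loc_times))
        f.create_dataset("ret_times", data=np.asarray(ret_times))
        f.create_dataset("included", data=r.included.astype(int))
        f.create_dataset("peak_accuracy", data=r.peak_accuracy)
        f.create_dataset("peak_time", data=r.peak_time)
        f.create_dataset("retrieval_accuracy", data=r.retrieval_accuracy)
        f.create_dataset("accuracy_curves", data=r.accuracy_curves)
        s = f.create_group("sequenceness")
        s.create_dataset("lags_ms", data=r.sequenceness.lags_ms)
        s.create_dataset("zf", data=r.sequenceness.zf)
        s.create_dataset("zb", data=r.sequenceness.zb)
        s.create_dataset("null_f", data=r.sequenceness.null_f)
        s.create_dataset("null_b", data=r.sequenceness.null_b)
        s.attrs.update(
            max_threshold_f=r.sequenceness.max_threshold_f,
            pct95_threshold_f=r.sequenceness.pct95_threshold_f,
            max_threshold_b=r.sequenceness.max_threshold_b,
            pct95_threshold_b=r.sequenceness.pct95_threshold_b,
            mean_lag_stat_f=r.sequenceness.mean_lag_stat_f,
            mean_lag_p_f=r.sequenceness.mean_lag_p_f,
            mean_lag_stat_b=r.sequenceness.mean_lag_stat_b,
            mean_lag_p_b=r.sequenceness.mean_lag_p_b,
            performance_r=r.performance_r, performance_p=r.performance_p)
        re = f.create_group("reactivation")
        re.create_dataset("differential", data=r.differential)
        re.create_dataset("differential_p", data=r.differential_p)
        re.create_dataset("significant", data=r.significant_times.astype(int))
        re.create_dataset("profile_table", data=r.profile.table)
        re.attrs.update(peak_time=r.peak_reactivation_time,
                        anova_F=r.profile.anova.F,
                        anova_df_effect=r.profile.anova.df_effect,
                        anova_df_error=r.profile.anova.df_error,
                        anova_p=r.profile.anova.p)
        if r.pre_post is not None:
            re.attrs.update(pre_post_t=r.pre_post[0], pre_post_p=r.pre_post[1])


def _write_tsvs(out: Path, r: CohortResult, ret_times, loc_times) -> None:
    pd.DataFrame({
        "participant": np.arange(len(r.peak_accuracy)),
        "peak_accuracy": r.peak_accuracy,
        "peak_time": r.peak_time,
        "retrieval_accuracy": r.retrieval_accuracy,
        "included": r.included.astype(int),
    }).to_csv(out / "participants.tsv", sep="\t", index=False,
              float_format="%.6g")
    (out / "sequenceness.tsv").write_text(r.sequenceness.summary_tsv())
    pd.DataFrame({
        "time_s": np.asarray(ret_times),
        "differential": r.differential,
        "p": r.differential_p,
        "significant": r.significant_times.astype(int),
    }).to_csv(out / "differential.tsv", sep="\t", index=False,
              float_format="%.6g")
    prof = pd.DataFrame(r.profile.table,
                        columns=[f"distance_{d}" for d in r.profile.levels])
    prof.insert(0, "participant", r.profile.included)
    prof.to_csv(out / "distance_profile.tsv", sep="\t", index=False,
                float_format="%.6g")
    a = r.profile.anova
    pd.DataFrame([{
        "F": a.F, "df_effect": a.df_effect, "df_error": a.df_error, "p": a.p,
        "peak_time_s": r.peak_reactivation_time,
    }]).to_csv(out / "anova.tsv", sep="\t", index=False, float_format="%.6g")


def report(out_dir) -> None:
    """Regenerate the TSV summaries from the HDF5 results store."""
    out = Path(out_dir)
    with h5py.File(out / "results.h5", "r") as f:
        lags = f["sequenceness/lags_ms"][()]
        zf = f["sequenceness/zf"][()].mean(axis=0)
        zb = f["sequenceness/zb"][()].mean(axis=0)
        sa = f["sequenceness"].attrs
        lines = ["lag_ms\tzf\tzb\tpct95_f\tmax_f\tpct95_b\tmax_b"]
        for i, lag in enumerate(lags):
            lines.append("\t".join([
                f"{lag:.0f}", f"{zf[i]:.6g}", f"{zb[i]:.6g}",
                f"{sa['pct95_threshold_f']:.6g}", f"{sa['max_threshold_f']:.6g}",
                f"{sa['pct95_threshold_b']:.6g}", f"{sa['max_threshold_b']:.6g}"]))
        (out / "sequenceness.tsv").write_text("\n".join(lines) + "\n")
        pd.DataFrame({
            "participant": np.arange(len(f["peak_accuracy"])),
            "peak_accuracy": f["peak_accuracy"][()],
            "peak_time": f["peak_time"][()],
            "retrieval_accuracy": f["retrieval_accuracy"][()],
            "included": f["included"][()],
        }).to_csv(out / "participants.tsv", sep="\t", index=False,
                  float_format="%.6g")
        re = f["reactivation"]
        pd.DataFrame({
            "time_s": f["ret_times"][()],
            "differential": re["differential"][()],
            "p": re["differential_p"][()],
            "significant": re["significant"][()],
        }).to_csv(out / "differential.tsv", sep="\t", index=False,
                  float_format="%.6g")
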