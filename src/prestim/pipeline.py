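"""End-to-end orchestration: simulate -> preprocess -> TFR -> statistics.

The pipeline streams subjects (epoch arrays are large), keeping only the
small per-subject products in memory: condition-averaged dB maps for the
univariate cluster statistics, and time-averaged raw-power feature matrices
for the decoding analyses.  Every random stage has an explicit seed, the
full configuration is serialized into the results, and a rerun with the
same configuration and seeds produces byte-identical results (timestamps
live only in the log).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .behavior import (behavior_table, compare_bias, negativity_bias,
                       questionnaire_correlations)
from .cluster import cluster_permutation
from .decoding import (DecodeConfig, binomial_accuracy_test, decode_features,
                       group_lopocv_features, group_ttest_vs_chance,
                       peak_accuracy, previous_label_control_features,
                       summarize_previous_control)
from .epochs import common_average_reference, equalize_trials, inclusion_check, select_rated
from .simulate import SimConfig, simulate_subject
from .tfr import condition_average, db_baseline, sliding_hann_spectrogram

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name for context."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """All stage parameter blocks plus explicit seeds.

    ``simulate`` holds :class:`~prestim.simulate.SimConfig` fields;
    ``tfr``, ``cluster`` and ``decode`` hold the corresponding stage
    parameters.  The config is serialized verbatim into every output.
    """

    simulate: dict = field(default_factory=dict)
    tfr: dict = field(default_factory=lambda: {
        "fmax": 60.0, "window_length": 500.0, "baseline": (-1500.0, -500.0)})
    cluster: dict = field(default_factory=lambda: {
        "n_perm": 2000, "alpha": 0.025,
        "threshold_mode": "nonparametric_individual",
        "tmin": -500.0, "tmax": 1500.0, "fmax": 60.0, "seed": 11})
    decode: dict = field(default_factory=lambda: {
        "window": (-1000.0, -200.0), "fmax": 60.0, "mode": "single",
        "seed": 13})
    equalize_seed: int = 7
    min_trials: int = 10

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        for key, value in raw.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config key {key!r}")
            current = getattr(cfg, key)
            if isinstance(current, dict) and isinstance(value, dict):
                current.update(value)
            else:
                setattr(cfg, key, value)
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _stage_seed(base: int, *key) -> int:
    ss = np.random.SeedSequence(entropy=base, spawn_key=tuple(key))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return f if np.isfinite(f) else None
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    return obj


def _process_subject(subject_index: int, sim_config: SimConfig,
                     config: RunConfig, log) -> dict | None:
    """One participant: preprocess both experiments and reduce to the
    small per-subject products.  Returns None if the subject fails the
    trial-count inclusion rule in either experiment."""
    subj = simulate_subject(sim_config, subject_index)
    fmax = float(config.tfr["fmax"])
    wl = float(config.tfr["window_length"])
    baseline = tuple(config.tfr["baseline"])
    freqs = np.arange(2.0, fmax + 0.5, 1.0)
    lo, hi = subj.exp1.times[0], subj.exp1.times[-1]
    centers = np.arange(lo + wl / 2.0, hi - wl / 2.0 + 1e-9, 50.0)
    decode_cfg = DecodeConfig(**{**config.decode,
                                 "seed": _stage_seed(config.decode.get("seed", 13),
                                                     subject_index)})

    out = {"subject": subject_index, "behavior": subj.behavior,
           "experiments": {}, "included": True}
    for exp_id, epochs in ((1, subj.exp1), (2, subj.exp2)):
        epochs = common_average_reference(epochs)
        ratings = epochs.metadata["rating"].to_numpy()
        sel = {lab: select_rated(epochs, {lab}) for lab in ("negative", "positive")}
        try:
            eq = equalize_trials(sel, seed=_stage_seed(config.equalize_seed,
                                                       subject_index, exp_id))
        except ValueError:
            out["included"] = False
            log.warning("subject %d exp %d: empty rating class", subject_index, exp_id)
            continue
        counts = {lab: len(s) for lab, s in eq.items()}
        if not inclusion_check(counts, minimum=config.min_trials):
            out["included"] = False
            log.info("subject %d exp %d excluded (counts %s)", subject_index,
                     exp_id, counts)
            continue

        tfr = sliding_hann_spectrogram(epochs, freqs=freqs, times=centers,
                                       window_length=wl)
        tfr_db = db_baseline(tfr, baseline=baseline)
        cond = condition_average(tfr_db, eq)
        diff = cond["negative"].power[0] - cond["positive"].power[0]

        eq_idx = np.sort(np.concatenate([eq["negative"].indices,
                                         eq["positive"].indices]))
        from .decoding import _prestimulus_features
        X_all, _ = _prestimulus_features(tfr, decode_cfg)

        entry = {
            "ratings": ratings,
            "counts_equalized": counts,
            "diff_map": diff,
            "cond_maps": {lab: cond[lab].power[0] for lab in cond},
            "X_eq": X_all[eq_idx], "y_eq": ratings[eq_idx],
            "bias_pct": negativity_bias(
                {lab: int(np.sum(ratings == lab))
                 for lab in ("negative", "positive", "neutral", "missed")}),
        }
        if exp_id == 1:
            prev = epochs.metadata["previous_rating"].to_numpy()
            usable = np.isin(ratings, ("negative", "positive")) \
                & np.isin(prev, ("negative", "positive"))
            entry["X_usable"] = X_all[usable]
            entry["cur_usable"] = ratings[usable]
            entry["prev_usable"] = prev[usable]
        out["experiments"][exp_id] = entry
    out["tfr_axes"] = {"freqs": freqs, "times": centers,
                       "channels": sim_config.montage().channels}
    out["decode_cfg"] = decode_cfg
    return out


def _cluster_stage(subjects, config: RunConfig, montage) -> dict:
    cl = config.cluster
    results = {}
    axes0 = subjects[0]["tfr_axes"]
    f_sel = (axes0["freqs"] >= 2.0) & (axes0["freqs"] <= float(cl["fmax"]))
    t_sel = (axes0["times"] >= float(cl["tmin"])) & (axes0["times"] <= float(cl["tmax"]))

    def _restrict(m):
        return m[:, f_sel][..., t_sel]

    for exp_id in (1, 2):
        usable = [s for s in subjects if exp_id in s["experiments"]]
        if len(usable) < 2:
            results[f"exp{exp_id}"] = None
            continue
        a = np.stack([_restrict(s["experiments"][exp_id]["cond_maps"]["negative"])
                      for s in usable])
        b = np.stack([_restrict(s["experiments"][exp_id]["cond_maps"]["positive"])
                      for s in usable])
        res = cluster_permutation((a, b), design="paired",
                                  n_perm=int(cl["n_perm"]), alpha=float(cl["alpha"]),
                                  threshold_mode=cl["threshold_mode"],
                                  seed=_stage_seed(cl.get("seed", 11), exp_id),
                                  adjacency=montage.adjacency)
        results[f"exp{exp_id}"] = _summarize_cluster(res)

    both = [s for s in subjects if len(s["experiments"]) == 2]
    if len(both) >= 3:
        diff = np.stack([(_restrict(s["experiments"][1]["diff_map"])
                          + _restrict(s["experiments"][2]["diff_map"])) / 2.0
                         for s in both])
        bias = np.array([_combined_bias(s) for s in both])
        res = cluster_permutation((diff, bias), design="covariate",
                                  n_perm=int(cl["n_perm"]), alpha=float(cl["alpha"]),
                                  threshold_mode=cl["threshold_mode"],
                                  seed=_stage_seed(cl.get("seed", 11), 3),
                                  adjacency=montage.adjacency)
        results["bias_covariate"] = _summarize_cluster(res)
    else:
        results["bias_covariate"] = None
    return results


def _combined_bias(subject) -> float:
    """Negativity bias pooled over both experiments' ratings."""
    counts = {lab: 0 for lab in ("negative", "positive", "neutral", "missed")}
    for exp in subject["experiments"].values():
        for lab in counts:
            counts[lab] += int(np.sum(exp["ratings"] == lab))
    return negativity_bias(counts)


def _summarize_cluster(res) -> dict:
    sig = res.significant()
    return {
        "n_clusters": len(res.clusters),
        "min_p": res.min_p,
        "n_significant": len(sig),
        "significant": [{"sign": c.sign, "size": c.size, "mass": c.mass,
                         "p": c.p} for c in sig],
        "n_permutations": res.n_permutations,
        "seed": res.seed,
    }


def _decoding_stage(subjects, config: RunConfig, log) -> dict:
    both = [s for s in subjects if len(s["experiments"]) == 2]
    per_subject = []
    features = []
    for s in both:
        e1, e2 = s["experiments"][1], s["experiments"][2]
        cfg = s["decode_cfg"]
        n_ch = len(s["tfr_axes"]["channels"])
        res = decode_features(e1["X_eq"], e1["y_eq"], e2["X_eq"], e2["y_eq"],
                              cfg, n_channels=n_ch)
        per_subject.append({"subject": s["subject"], "peak": res.peak,
                            "accuracy": res.accuracies.tolist(),
                            "p": res.p_values.tolist(),
                            "n_test": int(res.n_test[0])})
        features.append((e1["X_eq"], e1["y_eq"], e2["X_eq"], e2["y_eq"]))
    peaks = np.array([r["peak"] for r in per_subject])
    t, df, p = group_ttest_vs_chance(peaks)
    out = {"subject_level": {"per_subject": per_subject,
                             "mean_peak": float(peaks.mean()),
                             "sd_peak": float(peaks.std(ddof=1)) if len(peaks) > 1 else None,
                             "t_vs_chance": t, "df": df, "p": p}}

    cfg0 = both[0]["decode_cfg"]
    _, lopo_peaks = group_lopocv_features(features, cfg0)
    t, df, p = group_ttest_vs_chance(lopo_peaks)
    out["group_lopocv"] = {"peaks": lopo_peaks.tolist(),
                           "mean_peak": float(lopo_peaks.mean()),
                           "t_vs_chance": t, "df": df, "p": p}

    pairs = []
    for s in both:
        e1 = s["experiments"][1]
        res = previous_label_control_features(e1["X_usable"], e1["cur_usable"],
                                              e1["prev_usable"], s["decode_cfg"],
                                              min_trials=config.min_trials)
        if res is not None:
            pairs.append(res)
        else:
            log.info("subject %d skipped in previous-rating control", s["subject"])
    prev = summarize_previous_control(pairs)
    out["previous_control"] = {
        "mean_acc_previous": float(prev["acc_previous"].mean()),
        "mean_acc_current": float(prev["acc_current"].mean()),
        "t": prev["t"], "df": prev["df"], "p": prev["p"],
        "n_subjects": len(pairs),
    }
    return out


def _behavior_stage(subjects) -> dict:
    records = []
    for s in subjects:
        for exp_id, exp in s["experiments"].items():
            records.append({"subject": s["subject"], "experiment": exp_id,
                            "ratings": exp["ratings"],
                            "bdi2": s["behavior"]["bdi2"],
                            "stai_s": s["behavior"]["stai_s"],
                            "stai_t": s["behavior"]["stai_t"]})
    table = behavior_table(records)
    out = {"table": table}
    summary = {}
    for exp_id in (1, 2):
        sub = table[table["experiment"] == exp_id]
        summary[f"exp{exp_id}"] = {
            "n": int(len(sub)),
            "mean_bias_pct": float(sub["negativity_bias_pct"].mean()),
            "sd_bias_pct": float(sub["negativity_bias_pct"].std(ddof=1)),
        }
    both = [s for s in subjects if len(s["experiments"]) == 2]
    b1 = [s["experiments"][1]["bias_pct"] for s in both]
    b2 = [s["experiments"][2]["bias_pct"] for s in both]
    t, df, p = compare_bias(b1, b2)
    summary["bias_comparison"] = {"t": t, "df": df, "p": p, "n": len(both)}
    for exp_id in (1, 2):
        sub = table[table["experiment"] == exp_id]
        corr = questionnaire_correlations(
            sub["negativity_bias_pct"], sub[["bdi2", "stai_s", "stai_t"]])
        summary[f"questionnaire_corr_exp{exp_id}"] = corr.to_dict(orient="records")
    out["summary"] = summary
    return out


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute the full analysis on a simulated cohort and write the report.

    Writes ``results.json`` (machine readable, deterministic),
    ``behavior.tsv``, ``clusters.tsv``, ``decoding.json``, ``report.txt``
    and ``pipeline.log`` under ``out_dir``; returns the results dict.
    Stage failures raise :class:`PipelineError` naming the stage, with
    partial outputs preserved.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log = logging.getLogger("prestim.pipeline")
    log.setLevel(logging.INFO)
    handler = logging.FileHandler(out_dir / "pipeline.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    results = {"version": __version__, "python": sys.version.split()[0],
               "config": _jsonable(config.to_dict()), "stages": {}}
    try:
        stage = "simulate/preprocess/tfr"
        sim_config = SimConfig(**config.simulate)
        montage = sim_config.montage()
        log.info("simulating %d subjects, %d channels, seed %d",
                 sim_config.n_subjects, montage.n_channels, sim_config.seed)
        subjects = []
        for i in range(sim_config.n_subjects):
            s = _process_subject(i, sim_config, config, log)
            if s is not None:
                subjects.append(s)
        results["stages"]["preprocess"] = {
            "n_subjects": len(subjects),
            "n_both_experiments": sum(len(s["experiments"]) == 2 for s in subjects),
        }

        stage = "cluster_stats"
        results["stages"]["cluster"] = _jsonable(
            _cluster_stage(subjects, config, montage))

        stage = "decoding"
        results["stages"]["decoding"] = _jsonable(
            _decoding_stage(subjects, config, log))

        stage = "behavior"
        behavior = _behavior_stage(subjects)
        results["stages"]["behavior"] = _jsonable(behavior["summary"])

        stage = "report"
        behavior["table"].to_csv(out_dir / "behavior.tsv", sep="\t", index=False)
        _write_cluster_tsv(out_dir / "clusters.tsv", results["stages"]["cluster"])
        (out_dir / "decoding.json").write_text(
            json.dumps(results["stages"]["decoding"], indent=1))
        (out_dir / "results.json").write_text(json.dumps(results, indent=1))
        (out_dir / "report.txt").write_text(_render_report(results))
    except Exception as exc:
        (out_dir / "results.json").write_text(json.dumps(results, indent=1))
        log.error("stage %s failed: %s", stage, exc)
        raise PipelineError(stage, str(exc)) from exc
    finally:
        log.removeHandler(handler)
        handler.close()
    return results


def _write_cluster_tsv(path, cluster_results: dict) -> None:
    rows = []
    for name, res in cluster_results.items():
        if res is None:
            continue
        for i, c in enumerate(res["significant"]):
            rows.append({"analysis": name, "cluster": i, "sign": c["sign"],
                         "size": c["size"], "mass": c["mass"], "p": c["p"]})
    pd.DataFrame(rows, columns=["analysis", "cluster", "sign", "size",
                                "mass", "p"]).to_csv(path, sep="\t", index=False)


def _render_report(results: dict) -> str:
    """Plain-text report; numbers are taken verbatim from the results dict."""
    lines = ["prestim pipeline report", "=" * 40, ""]
    st = results["stages"]
    lines.append("[preprocess]")
    lines.append(f"  subjects analyzed: {st['preprocess']['n_subjects']}")
    lines.append(f"  with both experiments: {st['preprocess']['n_both_experiments']}")
    lines.append("")
    lines.append("[behavior]")
    for exp in ("exp1", "exp2"):
        s = st["behavior"][exp]
        lines.append(f"  {exp}: negativity bias {s['mean_bias_pct']:.1f}% "
                     f"(SD {s['sd_bias_pct']:.1f}, N={s['n']})")
    bc = st["behavior"]["bias_comparison"]
    lines.append(f"  paired t (exp1 vs exp2): t={bc['t']:.2f}, df={bc['df']}, "
                 f"p={bc['p']:.4g}")
    lines.append("")
    lines.append("[cluster statistics]")
    for name, res in st["cluster"].items():
        if res is None:
            lines.append(f"  {name}: not run (too few subjects)")
        else:
            lines.append(f"  {name}: {res['n_significant']} significant "
                         f"cluster(s), min p = {res['min_p']:.4g}")
    lines.append("")
    lines.append("[decoding]")
    sl = st["decoding"]["subject_level"]
    lines.append(f"  within-subject cross-experiment: mean peak accuracy "
                 f"{sl['mean_peak']:.3f}, t={sl['t_vs_chance']:.2f}, "
                 f"p={sl['p']:.4g}")
    gl = st["decoding"]["group_lopocv"]
    lines.append(f"  group LOPOCV: mean peak accuracy {gl['mean_peak']:.3f}, "
                 f"t={gl['t_vs_chance']:.2f}, p={gl['p']:.4g}")
    pc = st["decoding"]["previous_control"]
    lines.append(f"  previous-rating control: acc(prev)={pc['mean_acc_previous']:.3f}, "
                 f"acc(current)={pc['mean_acc_current']:.3f}, t={pc['t']:.2f}, "
                 f"p={pc['p']:.4g}")
    lines.append("")
    return "\n".join(lines)
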