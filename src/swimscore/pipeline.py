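"""End-to-end orchestration: tracks -> kinematics -> patterns -> scores
-> cohort statistics -> report artifacts."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io import (BoxGeometry, RawTrack, TrialDesign, Trajectory, recode,
                 read_track, write_summary_table, read_summary_table)
from .kinematics import summarize_windows, window_slice
from .patterns import (ClassifierParams, PatternSet, classify_patterns,
                       load_annotations, pattern_distribution)
from .scoring import (OlfactoryScore, RESPONDER_THRESHOLD,
                      cohort_response_summary, olfactory_score,
                      response_indexes, change_index, position_change_index)
from . import stats as ss

logger = logging.getLogger(__name__)


@dataclass
class AnalysisParams:
    """All tunables of the per-fish analysis, with assay defaults."""

    speed_step_s: float = 5.0
    rt_threshold_frac: float = 0.5
    literal_y_threshold: bool = False
    position_mode: str = "shift"
    responder_threshold: float = RESPONDER_THRESHOLD
    classifier: ClassifierParams = field(default_factory=ClassifierParams)
    seed: int = 0
    mc_reps: int = 10_000          # Monte-Carlo Fisher / permutation reps


def score_fish(raw: RawTrack, trial: TrialDesign, geom: BoxGeometry,
               params: AnalysisParams | None = None,
               annotation: tuple[PatternSet, PatternSet] | None = None
               ) -> dict:
    """Full per-fish analysis: one summary record.

    Manual pattern annotations, when given, override the rule-based
    classifier.
    """
    params = params or AnalysisParams()
    traj = recode(raw, geom, trial)
    kin_b, kin_a = summarize_windows(
        traj, trial, step_s=params.speed_step_s,
        threshold_frac=params.rt_threshold_frac,
        literal_y_threshold=params.literal_y_threshold)
    if annotation is not None:
        pat_b, pat_a = annotation
    else:
        pat_b = classify_patterns(
            window_slice(traj, *trial.window_before), params.classifier)
        pat_a = classify_patterns(
            window_slice(traj, *trial.window_after), params.classifier)
    idx = response_indexes(kin_b, kin_a, pat_b, pat_a,
                           position_mode=params.position_mode)
    score = olfactory_score(idx, threshold=params.responder_threshold)
    return {
        "fish_id": trial.fish_id, "morph": trial.morph, "day": trial.day,
        "odor": trial.odor, "conc_M": trial.syringe_concentration,
        "odor_side": trial.odor_side,
        "pos_before": kin_b.mean_position_x, "pos_after": kin_a.mean_position_x,
        "speed_before": kin_b.mean_speed, "speed_after": kin_a.mean_speed,
        "rtx_before": kin_b.round_trips_x, "rtx_after": kin_a.round_trips_x,
        "rty_before": kin_b.round_trips_y, "rty_after": kin_a.round_trips_y,
        "patterns_before": pat_b.serialize(),
        "patterns_after": pat_a.serialize(),
        "idx_pos": idx.idx_position, "idx_speed": idx.idx_speed,
        "idx_rt": idx.idx_roundtrips, "idx_pattern": idx.idx_pattern,
        "score": score.value, "responder": score.responder,
    }


def score_summary_records(df: pd.DataFrame,
                          params: AnalysisParams | None = None
                          ) -> pd.DataFrame:
    """Recompute indexes, score and responder call from window means.

    Input needs the before/after columns of the summary schema
    (``pos_*``, ``speed_*``, ``rtx_*``, ``rty_*``, ``patterns_*``); this
    is the direct-reprocessing path for precomputed per-fish tables.
    """
    params = params or AnalysisParams()
    out = df.copy()
    idx_pos, idx_speed, idx_rt, idx_pat, score, resp = [], [], [], [], [], []
    for _, r in df.iterrows():
        ip = position_change_index(r["pos_before"], r["pos_after"])
        isp = change_index(r["speed_before"], r["speed_after"])
        irt = change_index(r["rtx_before"] + r["rty_before"],
                           r["rtx_after"] + r["rty_after"])
        pb = PatternSet.parse(str(r["patterns_before"]))
        pa = PatternSet.parse(str(r["patterns_after"]))
        from .patterns import pattern_change_index
        ipt = pattern_change_index(pb, pa)
        val = abs(ip) + abs(isp) + abs(irt) + ipt
        idx_pos.append(ip); idx_speed.append(isp); idx_rt.append(irt)
        idx_pat.append(ipt); score.append(val)
        resp.append(val > params.responder_threshold)
    out["idx_pos"], out["idx_speed"] = idx_pos, idx_speed
    out["idx_rt"], out["idx_pattern"] = idx_rt, idx_pat
    out["score"], out["responder"] = score, resp
    return out


def _group_key(rec: dict) -> str:
    return f"{rec['morph']}|{rec['odor']}|{rec['conc_M']:g}"


def cohort_statistics(records: list[dict],
                      params: AnalysisParams | None = None) -> dict:
    """Cohort-level report: responder summaries, paired tests on each
    kinematic parameter, Fisher tests and CA on pattern composition, and
    PVE of the score on baseline personality."""
    params = params or AnalysisParams()
    df = pd.DataFrame(records)
    df["group"] = [_group_key(r) for r in records]
    report: dict = {"groups": {}, "tests": [], "seed": params.seed}

    scores_by_group = {
        g: [OlfactoryScore(value=v, threshold=params.responder_threshold,
                           responder=v > params.responder_threshold)
            for v in sub["score"]]
        for g, sub in df.groupby("group")
    }
    report["groups"] = cohort_response_summary(scores_by_group)

    for g, sub in df.groupby("group"):
        for name, (b, a) in {
            "position": ("pos_before", "pos_after"),
            "speed": ("speed_before", "speed_after"),
            "round_trips_x": ("rtx_before", "rtx_after"),
            "round_trips_y": ("rty_before", "rty_after"),
        }.items():
            if len(sub) >= 3:
                try:
                    p = ss.paired_rank_test(sub[b].to_numpy(),
                                            sub[a].to_numpy())
                    report["tests"].append(ss.test_report(
                        f"wilcoxon_{name}", [g], int(len(sub)), None, p))
                except ValueError as e:
                    logger.info("paired test %s/%s skipped: %s", g, name, e)
        # pattern composition before vs after
        cohort = ([(f"{g}|before", PatternSet.parse(s))
                   for s in sub["patterns_before"]]
                  + [(f"{g}|after", PatternSet.parse(s))
                     for s in sub["patterns_after"]])
        table = pattern_distribution(cohort, granularity="combination")
        if table.counts.shape[0] >= 2 and table.counts.shape[1] >= 2:
            try:
                fr = ss.fisher_exact(table, mc_reps=params.mc_reps,
                                     seed=params.seed)
                report["tests"].append(ss.test_report(
                    "fisher_patterns_before_after", [g], int(len(sub)),
                    None, fr.p_value, adjustment=fr.method,
                    seed=params.seed))
            except ValueError as e:
                logger.info("fisher %s skipped: %s", g, e)
            try:
                ca = ss.correspondence_analysis(table)
                report.setdefault("ca", {})[g] = {
                    "total_inertia": ca.total_inertia,
                    "explained_inertia": ca.explained_inertia.tolist(),
                    "row_coords": ca.row_coords.to_dict(),
                }
            except ValueError:
                pass

    # PVE of score on baseline personality (pattern category and speed)
    pats = df["patterns_before"].to_numpy()
    scores = df["score"].to_numpy(float)
    _, counts = np.unique(pats, return_counts=True)
    if counts.size >= 2 and counts.min() >= 2:
        r = ss.pve(scores, pats, kind="categorical",
                   n_permutations=params.mc_reps, seed=params.seed)
        report["pve_baseline_pattern"] = asdict(r)
    if len(df) >= 4 and df["speed_before"].nunique() > 1 \
            and df["score"].nunique() > 1:
        r = ss.pve(scores, df["speed_before"].to_numpy(float),
                   kind="continuous", n_permutations=params.mc_reps,
                   seed=params.seed)
        report["pve_baseline_speed"] = asdict(r)
        rho, p = ss.spearman_t(df["speed_before"].to_numpy(float), scores)
        report["spearman_score_vs_baseline_speed"] = {"rho": rho, "p": p}
    return report


# ------------------------------------------------------------- run config

@dataclass
class RunConfig:
    """Structured configuration of one pipeline run (YAML-loadable)."""

    tracks_dir: str = "."
    trials_table: str = "trials.tsv"
    annotations: str | None = None
    output_dir: str = "out"
    geometry: dict = field(default_factory=dict)
    params: AnalysisParams = field(default_factory=AnalysisParams)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        params = raw.pop("params", {})
        classifier = params.pop("classifier", {})
        cfg = cls(**{k: v for k, v in raw.items()
                     if k in cls.__dataclass_fields__})
        cfg.params = AnalysisParams(
            classifier=ClassifierParams(**classifier), **params)
        cfg.geometry = raw.get("geometry", {})
        return cfg

    def box_geometry(self) -> BoxGeometry:
        g = dict(self.geometry)
        corners = g.pop("corners", None)
        if corners:
            return BoxGeometry.from_corners(
                [tuple(c) for c in corners], **g)
        if "px_x" in g:
            g["px_x"] = tuple(g["px_x"])
        if "px_y" in g:
            g["px_y"] = tuple(g["px_y"])
        return BoxGeometry(**g)


def read_trials_table(path) -> list[TrialDesign]:
    df = pd.read_csv(path, sep="\t")
    need = {"fish_id", "morph", "day", "odor", "conc_M", "odor_side"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"trials table missing column(s): {sorted(missing)}")
    return [
        TrialDesign(fish_id=str(r.fish_id), morph=str(r.morph),
                    odor=str(r.odor), syringe_concentration=float(r.conc_M),
                    odor_side=str(r.odor_side), day=int(r.day))
        for r in df.itertuples()
    ]


def run_analysis(config: RunConfig) -> dict:
    """Run the full pipeline from a config; write all report artifacts.

    Deterministic given identical inputs; on any stage error the partial
    outputs are removed and the error re-raised with the stage named.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    artifacts = [out_dir / "summary.tsv", out_dir / "cohort.json",
                 out_dir / "run_log.json"]
    stage = "validate"
    try:
        trials_path = Path(config.trials_table)
        if not trials_path.exists():
            raise FileNotFoundError(f"trials table not found: {trials_path}")
        trials = read_trials_table(trials_path)
        geom = config.box_geometry()
        annotations = {}
        if config.annotations:
            with open(config.annotations) as fh:
                annotations = load_annotations(fh)
        stage = "per-fish analysis"
        records = []
        for trial in trials:
            track_path = Path(config.tracks_dir) / f"{trial.fish_id}.csv"
            with open(track_path) as fh:
                raw = read_track(fh, fish_id=trial.fish_id)
            records.append(score_fish(
                raw, trial, geom, config.params,
                annotation=annotations.get(trial.fish_id)))
        stage = "cohort statistics"
        report = cohort_statistics(records, config.params)
        stage = "write artifacts"
        with open(out_dir / "summary.tsv", "w") as fh:
            write_summary_table(records, fh)
        with open(out_dir / "cohort.json", "w") as fh:
            json.dump(report, fh, indent=2, default=float)
        cfg_hash = hashlib.sha256(
            json.dumps(asdict(config.params), sort_keys=True,
                       default=str).encode()).hexdigest()[:16]
        with open(out_dir / "run_log.json", "w") as fh:
            json.dump({"version": __version__, "config_hash": cfg_hash,
                       "seed": config.params.seed,
                       "n_fish": len(records)}, fh, indent=2)
        return {"records": records, "report": report, "out_dir": str(out_dir)}
    except Exception as e:
        for a in artifacts:
            a.unlink(missing_ok=True)
        raise RuntimeError(f"analysis failed at stage '{stage}': {e}") from e
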