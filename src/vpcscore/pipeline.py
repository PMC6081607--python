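"""End-to-end orchestration: simulate, score both arms, agree, correlate.

``run_pipeline`` mirrors the analysis order of the assessment: inter-rater
agreement of the frame coding, cross-camera correlation of novelty
preference at subject and trial level, then correlations of each arm's
overall NP with the cognitive composites and components, with the
independent Fisher r-to-z comparison between the two arms' validity
coefficients.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .composites import compute_composites, norms_from_mapping
from .framecode_scoring import score_trials_frames
from .highrate_scoring import FilterParams, score_trials_highrate
from .io import load_cohort, write_cohort
from .stats import (UndefinedStatisticError, fisher_compare,
                    krippendorff_nominal, spearman, strength_category)
from .synthetic_data import SYNTHETIC_NORMS, CohortParams, simulate_cohort
from .types import AOIPair, Rect, SubjectNP


@dataclass
class RunConfig:
    """Everything a full pipeline run needs, loadable from YAML."""

    out_dir: str = "vpc_run"
    simulate: bool = True
    cohort: CohortParams = field(
        default_factory=lambda: CohortParams(n_subjects=44))
    data_dir: str | None = None      # used when simulate=False
    filter_params: FilterParams = field(default_factory=FilterParams)
    aois: AOIPair = field(default_factory=AOIPair)
    norms: dict[str, dict] = field(default_factory=lambda: dict(SYNTHETIC_NORMS))
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs: dict = {}
        for key in ("out_dir", "simulate", "data_dir", "log_level"):
            if key in raw:
                kwargs[key] = raw[key]
        if "cohort" in raw:
            cohort = dict(raw["cohort"])
            if "subject_np_dist" in cohort:
                cohort["subject_np_dist"] = tuple(cohort["subject_np_dist"])
            kwargs["cohort"] = CohortParams(**cohort)
        if "filter_params" in raw:
            kwargs["filter_params"] = FilterParams(**raw["filter_params"])
        if "aois" in raw:
            a = raw["aois"]
            kwargs["aois"] = AOIPair(
                left_box=Rect(*a["left_box"]), right_box=Rect(*a["right_box"]),
                margin=a.get("margin", 0.10))
        if "norms" in raw:
            kwargs["norms"] = raw["norms"]
        return cls(**kwargs)


def rater_matrix_from_codes(codes: pd.DataFrame) -> list[list[str]]:
    """Units-by-raters matrix: one unit per (subject, trial, frame)."""
    wide = codes.pivot_table(index=["subject_id", "trial", "frame"],
                             columns="rater", values="code", aggfunc="first")
    return wide.to_numpy(dtype=object).tolist()


def _trial_table(subject_id: str, scores) -> pd.DataFrame:
    rows = []
    for s in scores:
        rows.append({
            "subject_id": subject_id, "trial": s.trial,
            "np": s.np_score, "novel_ms": s.novel_ms,
            "familiar_ms": s.familiar_ms,
            "n_novel": s.n_novel, "n_familiar": s.n_familiar,
            "n_neither": s.n_neither,
            "excluded": s.excluded, "reason": s.reason,
        })
    return pd.DataFrame(rows)


VALIDITY_MEASURES = ["pacc", "nihtb", "mmse_z", "lm_dr_z", "fcsrt_z",
                     "digit_symbol_z", "letter_fluency_z",
                     "category_fluency_z", "trails_a_z", "pvt_z", "psmt_z",
                     "flanker_z", "dccs_z"]


def correlate_with_composites(subjects_np: pd.DataFrame,
                              composites: pd.DataFrame) -> pd.DataFrame:
    """Validity table: NP of each camera arm against every cognitive measure.

    One row per measure with the Spearman rho and p for each arm, the
    independent two-tailed Fisher r-to-z comparison of the two
    coefficients, and Cohen strength labels.
    """
    merged = subjects_np.merge(composites, on="subject_id")
    rows = []
    for measure in VALIDITY_MEASURES:
        if measure not in merged.columns:
            continue
        row: dict = {"measure": measure}
        results = {}
        for arm, col in (("highrate", "mean_np_highrate"),
                         ("frames", "mean_np_frames")):
            try:
                res = spearman(merged[col], merged[measure])
            except UndefinedStatisticError:
                res = None
            results[arm] = res
            row[f"r_{arm}"] = res.rho if res else math.nan
            row[f"p_{arm}"] = res.p if res else math.nan
            row[f"n_{arm}"] = res.n if res else 0
            row[f"strength_{arm}"] = (strength_category(res.rho, "cohen_r")
                                      if res else "")
        hr, fr = results["highrate"], results["frames"]
        # a degenerate rho of +/-1 (tiny n) has no Fisher transform
        if (hr and fr and max(abs(hr.rho), abs(fr.rho)) < 1.0
                and min(hr.n, fr.n) > 3):
            cmp_ = fisher_compare(hr.rho, hr.n, fr.rho, fr.n)
            row["comparison_z"] = cmp_.z
            row["comparison_p"] = cmp_.p
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and write the report bundle.

    Returns a dict with the key results (agreement coefficient, subject-
    and trial-level cross-camera correlations, validity table) alongside
    the paths written.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "simulate" if config.simulate else "load"
    try:
        if config.simulate:
            datasets, truth = simulate_cohort(config.cohort, config.aois)
            write_cohort(datasets, truth, out / "data")
            gaze = pd.concat([d.gaze.assign(subject_id=d.subject_id)
                              for d in datasets], ignore_index=True)
            codes = pd.concat([d.codes.assign(subject_id=d.subject_id)
                               for d in datasets], ignore_index=True)
            trials = {d.subject_id: d.trials for d in datasets}
            cognition = pd.DataFrame([{"subject_id": d.subject_id, **d.cognition}
                                      for d in datasets])
        else:
            if config.data_dir is None:
                raise ValueError("simulate=False requires data_dir")
            gaze, codes, trials, cognition = load_cohort(config.data_dir)

        stage = "score-highrate"
        hr_tables, fr_tables, subject_rows = [], [], []
        for subject_id, trial_meta in trials.items():
            sub_gaze = gaze[gaze["subject_id"] == subject_id]
            sub_codes = codes[codes["subject_id"] == subject_id]
            hr_scores = score_trials_highrate(
                sub_gaze, trial_meta, config.aois, config.filter_params,
                sample_hz=config.cohort.sample_hz)
            fr_scores = score_trials_frames(sub_codes, trial_meta)
            hr_tables.append(_trial_table(subject_id, hr_scores))
            fr_tables.append(_trial_table(subject_id, fr_scores))
            hr_np = SubjectNP.from_trials(subject_id, hr_scores)
            fr_np = SubjectNP.from_trials(subject_id, fr_scores)
            subject_rows.append({
                "subject_id": subject_id,
                "mean_np_highrate": hr_np.mean_np,
                "mean_np_frames": fr_np.mean_np,
                "n_retained_highrate": hr_np.n_retained,
                "n_retained_frames": fr_np.n_retained,
            })
        scores_hr = pd.concat(hr_tables, ignore_index=True)
        scores_fr = pd.concat(fr_tables, ignore_index=True)
        subjects_np = pd.DataFrame(subject_rows)

        stage = "agree"
        alpha = krippendorff_nominal(rater_matrix_from_codes(codes))

        stage = "correlate"
        subj_cc = spearman(subjects_np["mean_np_highrate"],
                           subjects_np["mean_np_frames"])
        pooled = scores_hr.merge(scores_fr, on=["subject_id", "trial"],
                                 suffixes=("_hr", "_fr"))
        pooled = pooled[~pooled["excluded_hr"] & ~pooled["excluded_fr"]].dropna(
            subset=["np_hr", "np_fr"])
        trial_cc = spearman(pooled["np_hr"], pooled["np_fr"])
        composites = compute_composites(cognition,
                                        norms_from_mapping(config.norms))
        validity = correlate_with_composites(subjects_np, composites)

        stage = "report"
        scores_hr.to_csv(out / "scores_highrate.csv", index=False)
        scores_fr.to_csv(out / "scores_frames.csv", index=False)
        subjects_np.to_csv(out / "subjects_np.csv", index=False)
        composites.to_csv(out / "composites.csv", index=False)
        validity.to_csv(out / "validity_table.tsv", sep="\t", index=False)
        agreement = {
            "krippendorff_alpha": alpha,
            "alias": "krippendorff_kappa",
            "strength": strength_category(alpha, "kappa"),
            "n_raters": config.cohort.n_raters,
        }
        (out / "agreement.json").write_text(json.dumps(agreement, indent=1))
        summary = {
            "agreement": agreement,
            "cross_camera_subject": {"rho": subj_cc.rho, "n": subj_cc.n,
                                     "p": subj_cc.p},
            "cross_camera_trial": {"rho": trial_cc.rho, "n": trial_cc.n,
                                   "p": trial_cc.p},
        }
        manifest = _manifest(config)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        (out / "summary.json").write_text(json.dumps(summary, indent=1))
        summary["validity"] = validity
        summary["subjects_np"] = subjects_np
        summary["manifest"] = manifest
        return summary
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc


def _manifest(config: RunConfig) -> dict:
    payload = {
        "package": "vpcscore",
        "version": __version__,
        "seed": config.cohort.seed,
        "cohort": dataclasses.asdict(config.cohort),
        "filter_params": dataclasses.asdict(config.filter_params),
    }
    digest = hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()
    payload["config_sha256"] = digest
    return payload
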