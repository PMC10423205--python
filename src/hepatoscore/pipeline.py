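"""End-to-end orchestration: simulate/load, score, analyse, report.

A run produces, per patient, the full score panel, and at cohort level the
report tables of the study design: a characteristics table, the four-score
Pearson correlation matrix, group summaries and ROC analyses for the two
dichotomies (MELD <= 10 vs >= 11; cirrhosis vs none) on MELIF and ALBI, the
ALBI-grade stratification with one-way ANOVA on MELIF, and the two
grade-boundary ROC analyses (grade 1 vs 2, grade 2 vs 3) on MELIF.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from . import io as bundle_io
from . import stats
from .relaxometry import compute_rrt1
from .scoring import (
    BILIRUBIN_UMOL_PER_MG_DL,
    MelifParameters,
    PatientRecord,
    albi_grade,
    albi_score,
    child_pugh,
    meld_group,
    meld_score,
    round_half_away,
)
from .synthetic import CohortSpec, simulate_cohort

logger = logging.getLogger("hepatoscore")

#: score -> which end indicates the positive (diseased) class
SCORE_DIRECTIONS: dict[str, stats.Direction] = {
    "melif": "lower",
    "albi": "higher",
    "meld": "higher",
    "cp": "higher",
}


@dataclass
class RunConfig:
    """Configuration of one pipeline run (exactly one input source)."""

    source: Literal["simulate", "directory"]
    cohort_spec: CohortSpec | None = None
    bundle_dir: str | None = None
    out_dir: str = "hepatoscore_out"
    seed: int = 0
    aggregation: Literal["sum", "mean"] = "sum"
    volume_unit: Literal["ml", "l"] = "ml"
    meld_clamping: Literal["raw", "unos"] = "raw"
    ci_method: Literal["hanley", "delong"] = "hanley"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.source == "simulate" and self.cohort_spec is None:
            raise ValueError("simulate source needs a cohort_spec")
        if self.source == "directory" and self.bundle_dir is None:
            raise ValueError("directory source needs a bundle_dir")


@dataclass
class ReportBundle:
    scores: pd.DataFrame
    characteristics: pd.DataFrame | None = None
    correlations: pd.DataFrame | None = None
    group_summary: pd.DataFrame | None = None
    roc_summary: pd.DataFrame | None = None
    anova: pd.DataFrame | None = None
    out_dir: Path | None = None


def compute_score_table(cohort: pd.DataFrame, meld_clamping: str = "raw") -> pd.DataFrame:
    """Per-patient score panel recomputed from the blood panel.

    MELIF is taken from the cohort table (drawn, or image-derived upstream);
    ALBI, MELD and Child-Pugh are recomputed from the panel columns so every
    reported number is reproducible from the emitted per-patient data.
    """
    rows = []
    for _, row in cohort.iterrows():
        rec = PatientRecord(
            id=str(row["patient_id"]),
            height=float(row["height_m"]),
            weight=float(row["weight_kg"]),
            bilirubin=float(row["bilirubin_umol_L"]),
            albumin=float(row["albumin_g_L"]),
            creatinine=float(row["creatinine_mg_dL"]),
            inr=float(row["inr"]),
            ascites_grade=row.get("ascites_grade", "none"),
            encephalopathy_grade=row.get("encephalopathy_grade", "none"),
            cirrhosis=bool(row.get("cirrhosis", False)),
        )
        albi = albi_score(rec.bilirubin, rec.albumin)
        meld = meld_score(rec.bilirubin / BILIRUBIN_UMOL_PER_MG_DL, rec.inr,
                          rec.creatinine, clamping=meld_clamping)
        points, cls = child_pugh(rec)
        rows.append({
            "patient_id": rec.id,
            "group": row.get("group", ""),
            "melif": float(row["melif"]) if "melif" in row else np.nan,
            "albi": albi,
            "albi_grade": albi_grade(albi),
            "meld_raw": meld,
            "meld_rounded": round_half_away(meld),
            "meld_group": meld_group(meld),
            "cp_points": points,
            "cp_class": cls,
            "cirrhosis": rec.cirrhosis,
        })
    return pd.DataFrame(rows)


def _inclusive_quartiles(values) -> tuple[float, float, float]:
    """Median and Tukey-hinge quartiles (halves include the median when n odd)."""
    v = np.sort(np.asarray(values, dtype=float))
    n = len(v)
    med = float(np.median(v))
    half = (n + 1) // 2
    return float(np.median(v[:half])), med, float(np.median(v[n - half:]))


def summarize_cohort(scores: pd.DataFrame) -> pd.DataFrame:
    """Characteristics table: continuous mean (+- sd) — MELD as median (IQR)
    by the inclusive-quartile rule — categorical N (%), and a normality flag."""
    n = len(scores)
    rows = []

    def normal_p(x):
        try:
            return stats.dagostino_pearson(x)[1]
        except ValueError:
            return np.nan

    for name in ("melif", "albi"):
        x = scores[name].dropna()
        if len(x):
            rows.append({"variable": name, "presentation": "mean_sd",
                         "value": float(x.mean()), "spread_low": float(x.std(ddof=1)),
                         "spread_high": np.nan, "n": len(x),
                         "normality_p": normal_p(x)})
    q1, med, q3 = _inclusive_quartiles(scores["meld_rounded"])
    rows.append({"variable": "meld", "presentation": "median_iqr", "value": med,
                 "spread_low": q1, "spread_high": q3, "n": n,
                 "normality_p": normal_p(scores["meld_rounded"])})
    for name, series in (("albi_grade", scores["albi_grade"]),
                         ("cp_class", scores["cp_class"]),
                         ("cirrhosis", scores["cirrhosis"])):
        for level, count in series.value_counts().sort_index().items():
            rows.append({"variable": f"{name}={level}", "presentation": "n_pct",
                         "value": int(count), "spread_low": 100.0 * count / n,
                         "spread_high": np.nan, "n": n, "normality_p": np.nan})
    return pd.DataFrame(rows)


def correlation_matrix(scores: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlations among MELIF, ALBI, MELD and CP points.

    CP enters as its 5-15 point score (the class letters have no scale).
    """
    cols = {"melif": scores["melif"], "albi": scores["albi"],
            "meld": scores["meld_rounded"], "cp": scores["cp_points"]}
    rows = []
    names = list(cols)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            pair = pd.DataFrame({"a": cols[a], "b": cols[b]}).dropna()
            res = stats.pearson(pair["a"], pair["b"])
            rows.append({"score1": a, "score2": b, "r": res.r,
                         "ci_low": res.ci_low, "ci_high": res.ci_high,
                         "p_two_tailed": res.p_two_tailed, "n": res.n,
                         "interpretation": res.interpretation})
    return pd.DataFrame(rows)


def _roc_row(comparison, score_name, scores, labels, ci_method) -> dict | None:
    mask = np.isfinite(scores)
    scores, labels = scores[mask], labels[mask]
    if labels.sum() == 0 or (~labels).sum() == 0:
        logger.warning("skipping ROC %s on %s: a class is empty", comparison, score_name)
        return None
    res = stats.roc(scores, labels, SCORE_DIRECTIONS[score_name], ci_method=ci_method)
    return {"comparison": comparison, "score": score_name, "direction": res.direction,
            "n_positive": res.n_positive, "n_negative": res.n_negative,
            "auc": res.auc, "auc_ci_low": res.auc_ci_low, "auc_ci_high": res.auc_ci_high,
            "interpretation": res.interpretation, "cutoff": res.cutoff,
            "sensitivity_pct": res.cutoff_sensitivity,
            "specificity_pct": res.cutoff_specificity}


def group_summary(scores: pd.DataFrame) -> pd.DataFrame:
    """Mean (+- sd) of MELIF and ALBI per dichotomy group and ALBI grade."""
    rows = []
    strata = [("meld_group", scores["meld_group"]),
              ("cirrhosis", scores["cirrhosis"]),
              ("albi_grade", scores["albi_grade"])]
    for strat_name, strat in strata:
        for level, sub in scores.groupby(strat):
            for name in ("melif", "albi"):
                x = sub[name].dropna()
                if len(x) > 1:
                    rows.append({"stratification": strat_name, "group": str(level),
                                 "score": name, "n": len(x), "mean": float(x.mean()),
                                 "sd": float(x.std(ddof=1))})
    return pd.DataFrame(rows)


def analyze_scores(scores: pd.DataFrame, ci_method: str = "hanley") -> ReportBundle:
    """All cohort-level analyses on a per-patient score table."""
    n = len(scores)
    bundle = ReportBundle(scores=scores)
    if n < 3:
        logger.warning("cohort of %d patient(s): skipping analyses", n)
        return bundle

    bundle.characteristics = summarize_cohort(scores)
    bundle.correlations = correlation_matrix(scores)
    bundle.group_summary = group_summary(scores)

    melif = scores["melif"].to_numpy(dtype=float)
    albi = scores["albi"].to_numpy(dtype=float)
    roc_rows = []
    impaired = (scores["meld_group"] == "impaired").to_numpy()
    cirr = scores["cirrhosis"].to_numpy(dtype=bool)
    for comparison, labels in (("meld_dichotomy", impaired), ("cirrhosis", cirr)):
        for score_name, values in (("melif", melif), ("albi", albi)):
            row = _roc_row(comparison, score_name, values, labels, ci_method)
            if row:
                roc_rows.append(row)
    grade = scores["albi_grade"].to_numpy()
    for g_low, g_high in ((1, 2), (2, 3)):
        sel = (grade == g_low) | (grade == g_high)
        row = _roc_row(f"albi_grade_{g_low}_vs_{g_high}", "melif",
                       melif[sel], (grade[sel] == g_high), ci_method)
        if row:
            roc_rows.append(row)
    bundle.roc_summary = pd.DataFrame(roc_rows)

    grade_groups = [scores.loc[grade == g, "melif"].dropna() for g in (1, 2, 3)]
    labels = [f"grade{g}" for g in (1, 2, 3)]
    usable = [(g, lab) for g, lab in zip(grade_groups, labels) if len(g) >= 2]
    if len(usable) >= 2:
        res = stats.anova_oneway([g for g, _ in usable], [lab for _, lab in usable])
        anova_df = res.pairwise.copy()
        anova_df.insert(0, "f_statistic", res.f_statistic)
        anova_df.insert(1, "p_value", res.p_value)
        bundle.anova = anova_df
    else:
        logger.warning("fewer than two usable ALBI-grade groups: skipping ANOVA")
    return bundle


def _write_bundle(bundle: ReportBundle, out_dir: Path, manifest: dict) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle.out_dir = out_dir
    bundle.scores.to_csv(out_dir / "scores.csv", index=False)
    for name in ("characteristics", "correlations", "group_summary", "roc_summary", "anova"):
        df = getattr(bundle, name)
        if df is not None:
            df.to_csv(out_dir / f"{name}.csv", index=False)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))


def _manifest(config: RunConfig) -> dict:
    from . import __version__
    cfg = dataclasses.asdict(config)
    cfg_json = json.dumps(cfg, sort_keys=True, default=str)
    return {
        "config": cfg,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seed": config.seed,
        "hepatoscore_version": __version__,
        "quantile_rule": "inclusive (Tukey hinges)",
    }


def run(config: RunConfig) -> ReportBundle:
    """Execute one full pipeline run; deterministic for a fixed seed."""
    logging.basicConfig(level=config.log_level)
    out_dir = Path(config.out_dir)

    if config.source == "simulate":
        spec = dataclasses.replace(config.cohort_spec, seed=config.seed)
        cohort = simulate_cohort(spec)
        scores = compute_score_table(cohort, meld_clamping=config.meld_clamping)
        bundle = analyze_scores(scores, ci_method=config.ci_method)
        out_dir.mkdir(parents=True, exist_ok=True)
        cohort.to_csv(out_dir / "cohort.csv", index=False)
    else:
        data = bundle_io.read_phantom_bundle(config.bundle_dir)
        if data["patient"] is None:
            raise ValueError(f"imaging bundle {config.bundle_dir} lacks a patient record")
        fmap = compute_rrt1(data["t1_pre"], data["t1_post"], data["mask"])
        params = MelifParameters(aggregation=config.aggregation,
                                 volume_unit=config.volume_unit)
        from .scoring import score_patient
        panel = score_patient(data["patient"], fmap=fmap, mask=data["mask"],
                              params=params, meld_clamping=config.meld_clamping)
        scores = pd.DataFrame([{
            "patient_id": panel.id, "group": "", "melif": panel.melif,
            "albi": panel.albi, "albi_grade": panel.albi_grade,
            "meld_raw": panel.meld_raw, "meld_rounded": panel.meld_rounded,
            "meld_group": panel.meld_group, "cp_points": panel.child_pugh_points,
            "cp_class": panel.child_pugh_class, "cirrhosis": data["patient"].cirrhosis,
            "liver_volume_ml": panel.liver_volume_ml,
            "aggregation": panel.aggregation, "volume_unit": panel.volume_unit,
        }])
        bundle = analyze_scores(scores, ci_method=config.ci_method)
        out_dir.mkdir(parents=True, exist_ok=True)
        rr_export = np.where(fmap.valid_mask, fmap.rr, np.nan)
        bundle_io._save_nifti(out_dir / "functional_map.nii.gz", rr_export, fmap.geometry)

    _write_bundle(bundle, out_dir, _manifest(config))
    return bundle
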