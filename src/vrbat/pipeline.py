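"""End-to-end orchestration: sessions -> readout table -> statistics report.

``run_pipeline`` consumes session containers (or simulates a cohort), builds
one readout row per participant, and produces the full statistical report:
group tests on the three task readouts with post-hoc contrasts, mixed
repeated-measures ANOVAs on the detail readouts, trait-fear correlations,
the cross-task consistency matrix, and the questionnaire correlation table
with partial-correlation columns.  Exclusions (never entered the spider
side, eyes closed before the touch, missing pre-touch RR) are logged and
reduce the n of the affected analyses.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import readouts as ro
from . import stats as st
from .session import GROUPS, load_session
from .simulate import CohortConfig, generate_cohort

log = logging.getLogger("vrbat")

#: number of comparisons behind the conservative family-wise threshold
#: (three behavioral readouts crossed with 54 questionnaire scales)
BONFERRONI_M = 3 * 54


class PipelineConfig(BaseModel):
    """Run configuration; thresholds default to the standard analysis values."""

    input_dir: str | None = None
    out_dir: str = "vrbat_out"
    seed: int = 0
    alpha: float = Field(default=0.05, gt=0)
    bonferroni_m: int = Field(default=BONFERRONI_M, ge=1)
    touch_cap_s: float = Field(default=20.0, gt=0)
    accel_cap: int = Field(default=100, gt=0)
    glance_gap_s: float = Field(default=0.2, gt=0)
    pupil_window_s: float = Field(default=0.5, gt=0)
    rr_window_s: float = Field(default=1.0, gt=0)
    log_level: str = "INFO"
    simulate: dict = Field(default_factory=dict)

    def cohort_config(self) -> CohortConfig:
        kw = dict(self.simulate)
        kw.setdefault("seed", self.seed)
        return CohortConfig(**kw)


def _stars(p: float, alpha: float, bonf: float | None = None) -> str:
    if bonf is not None and p < bonf:
        return "****"
    for stars, cut in (("***", 0.001), ("**", 0.01), ("*", alpha)):
        if p < cut:
            return stars
    return ""


def _pair_tests(df: pd.DataFrame, col: str, parametric: bool) -> dict:
    out = {}
    for g1, g2 in (("phobic", "fearful"), ("phobic", "non_fearful"),
                   ("fearful", "non_fearful")):
        a = df.loc[df.group == g1, col].dropna().to_numpy()
        b = df.loc[df.group == g2, col].dropna().to_numpy()
        if a.size < 2 or b.size < 2:
            continue
        res = st.two_sample_t(a, b) if parametric else st.mann_whitney_u(a, b)
        out[f"{g1}_vs_{g2}"] = res.to_dict()
    return out


def _group_test(df: pd.DataFrame, col: str, parametric: bool) -> dict:
    groups = [df.loc[df.group == g, col].dropna().to_numpy() for g in GROUPS
              if (df.group == g).sum() >= 2]
    entry: dict = {"n": int(df[col].notna().sum())}
    if parametric:
        res = st.oneway_anova(groups)
        entry["anova"] = res.to_dict()
    else:
        entry["kruskal_wallis"] = st.kruskal_wallis(groups).to_dict()
    entry["post_hoc"] = _pair_tests(df, col, parametric)
    return entry


def _long_format(df: pd.DataFrame, spec: dict, value_name: str) -> pd.DataFrame:
    """Melt flat readout columns into subject x within-factor long format."""
    rows = []
    for _, r in df.iterrows():
        for col, factors in spec.items():
            rows.append({"subject": r.participant_id, "group": r.group,
                         value_name: r[col], **factors})
    out = pd.DataFrame(rows)
    complete = out.groupby("subject")[value_name].transform(lambda v: v.notna().all())
    return out[complete]


def _rm_anova_entry(long_df: pd.DataFrame, dv: str, within: list,
                    n_total: int) -> dict:
    kept = long_df["subject"].nunique()
    entry = {"n": kept, "exclusions": n_total - kept}
    groups_present = long_df.groupby("group")["subject"].nunique()
    if (groups_present >= 2).sum() < 2:
        entry["skipped"] = "fewer than two groups with two subjects"
        return entry
    res = st.mixed_rm_anova(long_df, dv=dv, subject="subject",
                            between="group", within=within)
    entry.update(res.to_dict())
    return entry


def compute_stats_report(df: pd.DataFrame, alpha: float = 0.05,
                         bonferroni_m: int = BONFERRONI_M) -> dict:
    """Build the full statistics report from a readout table."""
    n_total = len(df)
    bonf = st.bonferroni_threshold(alpha, bonferroni_m)
    report: dict = {
        "n": n_total,
        "alpha": alpha,
        "bonferroni": {"m": bonferroni_m, "threshold": bonf},
        "groups": df.group.value_counts().to_dict(),
    }

    enough_groups = (df.group.value_counts() >= 2).sum() >= 2
    if not enough_groups:
        log.warning("fewer than two groups with >= 2 participants; group statistics skipped")
        report["group_stats_skipped"] = True
        return report

    report["readout_group_tests"] = {
        "fishing": _group_test(df, "fishing_readout", parametric=True),
        "path_choice": _group_test(df, "path_choice_score", parametric=False),
        "touch_enemy": _group_test(df, "touch_readout", parametric=True),
    }

    # mixed rmANOVAs on the detail readouts
    rm: dict = {}
    rm["fishing_glances"] = _rm_anova_entry(
        _long_format(df, {
            "fishing_glances_spider": {"stimulus": "spider"},
            "fishing_glances_turtle": {"stimulus": "turtle"},
        }, "value"), "value", ["stimulus"], n_total)
    rm["fishing_orientation"] = _rm_anova_entry(
        _long_format(df, {
            "fishing_angle_spider": {"stimulus": "spider"},
            "fishing_angle_turtle": {"stimulus": "turtle"},
        }, "value"), "value", ["stimulus"], n_total)
    rm["fishing_rr_by_side"] = _rm_anova_entry(
        _long_format(df, {
            "fishing_rr_spider_side": {"stimulus": "spider"},
            "fishing_rr_turtle_side": {"stimulus": "turtle"},
        }, "value"), "value", ["stimulus"], n_total)
    rm["fishing_pupil_by_side"] = _rm_anova_entry(
        _long_format(df, {
            "fishing_pupil_spider_side": {"stimulus": "spider"},
            "fishing_pupil_turtle_side": {"stimulus": "turtle"},
        }, "value"), "value", ["stimulus"], n_total)

    thirds_spec = {
        f"thirds_{stim}{occ}_area{area}":
            {"stimulus": stim, "trial": occ, "area": area}
        for stim in ("spider", "turtle") for occ in (1, 2) for area in (1, 2, 3)
    }
    rm["touch_thirds"] = _rm_anova_entry(
        _long_format(df, thirds_spec, "value"), "value",
        ["trial", "stimulus", "area"], n_total)

    accel_spec = {f"accel_{stim}{occ}": {"stimulus": stim, "trial": occ}
                  for stim in ("spider", "turtle") for occ in (1, 2)}
    rm["touch_accel_changes"] = _rm_anova_entry(
        _long_format(df, accel_spec, "value"), "value",
        ["trial", "stimulus"], n_total)

    for what in ("pupil", "rr"):
        spec = {f"pre_touch_{what}_{stim}{occ}": {"stimulus": stim, "trial": occ}
                for stim in ("spider", "turtle") for occ in (1, 2)}
        rm[f"pre_touch_{what}"] = _rm_anova_entry(
            _long_format(df, spec, "value"), "value", ["trial", "stimulus"], n_total)
    report["rm_anovas"] = rm

    # trait-fear correlations with the three readouts
    fsq_corr = {}
    for name, col, method in (
        ("fishing", "fishing_readout", "pearson"),
        ("path_choice", "path_choice_score", "spearman"),
        ("touch_enemy", "touch_readout", "pearson"),
        ("fishing_glance_diff", "fishing_glance_diff", "pearson"),
    ):
        sub = df[[col, "fsq"]].dropna()
        fsq_corr[name] = st.correlation(sub[col], sub["fsq"], method).to_dict()
    report["fsq_correlations"] = fsq_corr

    # cross-task consistency
    cross = {}
    for (n1, c1), (n2, c2) in (
        (("fishing", "fishing_readout"), ("path_choice", "path_choice_score")),
        (("fishing", "fishing_readout"), ("touch_enemy", "touch_readout")),
        (("path_choice", "path_choice_score"), ("touch_enemy", "touch_readout")),
    ):
        sub = df[[c1, c2]].dropna()
        cross[f"{n1}_vs_{n2}"] = st.correlation(sub[c1], sub[c2], "spearman").to_dict()
    report["cross_task_spearman"] = cross

    # questionnaire table with partial-correlation columns
    df = df.assign(valence_diff=df.valence_turtle - df.valence_spider)
    scales = ["fsq", "valence_spider", "valence_turtle", "valence_diff"]
    table = {}
    for scale in scales:
        row = {}
        for name, col in (("fishing", "fishing_readout"),
                          ("path_choice", "path_choice_score"),
                          ("touch_enemy", "touch_readout")):
            cols = list(dict.fromkeys([col, scale, "fsq", "valence_spider"]))
            sub = df[cols].dropna()
            res = st.correlation(sub[col], sub[scale], "spearman")
            cell = {"r_s": res.statistic, "p": res.p,
                    "stars": _stars(res.p, alpha, bonf)}
            if scale != "fsq":
                cell["partial_fsq"] = st.partial_spearman(
                    sub[col], sub[scale], sub["fsq"]).to_dict()
            if scale != "valence_spider":
                cell["partial_valence_spider"] = st.partial_spearman(
                    sub[col], sub[scale], sub["valence_spider"]).to_dict()
            row[name] = cell
        table[scale] = row
    report["questionnaire_correlations"] = table

    report["exclusions"] = {
        "never_entered_spider_side": df.excluded_never_entered_spider_side.astype(bool).sum().item(),
        "eyes_closed_pre_touch": df.excluded_eyes_closed_pre_touch.astype(bool).sum().item(),
        "missing_pre_touch_rr": df.excluded_missing_rr.astype(bool).sum().item(),
    }
    return report


def load_sessions(input_dir: str | Path) -> list:
    """Load every session container under a directory; skip malformed ones."""
    root = Path(input_dir)
    sessions = []
    candidates = sorted(p for p in root.iterdir() if p.is_dir())
    for p in candidates:
        try:
            sessions.append(load_session(p))
        except Exception as exc:  # noqa: BLE001 - logged and skipped
            log.warning("skipping malformed session %s: %s", p.name, exc)
    if candidates and not sessions:
        raise RuntimeError(f"all session containers under {root} are malformed")
    return sessions


def run_pipeline(config: PipelineConfig) -> dict:
    """Simulate/load -> readouts.csv -> stats_report.json under ``out_dir``."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.input_dir:
        sessions = load_sessions(config.input_dir)
        log.info("loaded %d sessions from %s", len(sessions), config.input_dir)
    else:
        sessions, truth = generate_cohort(config.cohort_config())
        (out / "ground_truth.json").write_text(json.dumps(truth, indent=1))
        log.info("simulated %d sessions (seed %d)", len(sessions), config.seed)

    rows = []
    for s in sessions:
        try:
            rows.append(ro.compute_readout_row(s).to_flat_dict())
        except Exception as exc:  # noqa: BLE001
            log.warning("skipping participant %s: %s", s.participant_id, exc)
    if not rows:
        raise RuntimeError("no session yielded a readout row")
    df = pd.DataFrame(rows)
    readouts_csv = out / "readouts.csv"
    df.to_csv(readouts_csv, index=False)

    # recompute from the written table so the report is reproducible from it
    df2 = pd.read_csv(readouts_csv)
    report = compute_stats_report(df2, alpha=config.alpha,
                                  bonferroni_m=config.bonferroni_m)
    (out / "stats_report.json").write_text(json.dumps(report, indent=1))
    log.info("wrote %s and %s", readouts_csv, out / "stats_report.json")
    return {"readouts": readouts_csv, "stats_report": out / "stats_report.json",
            "n": len(df)}
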