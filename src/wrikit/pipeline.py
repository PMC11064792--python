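"""End-to-end orchestration: sessions -> features -> statistics -> classifiers.

Every stage logs its parameters; per-session failures are recorded in a
manifest and skipped rather than aborting the run; every output file embeds
the configuration hash and master seed so a report can always be traced back
to the exact settings that produced it.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from .classify import run_benchmark
from .config import RunConfig
from .io_model import SessionRecording, build_cohort_table, read_session, write_session
from .metrics import extract_features
from .simulate import STUDY_CELL_COUNTS, simulate_cohort
from .stats import art_anova_two_way, artc_posthoc, chi_square_independence

log = logging.getLogger("wrikit")

METRIC_COLUMNS = {"trt_s": "trt", "roa_deg": "roa", "symmetry": "symmetry"}


def load_sessions(data_dir: str | Path) -> list[SessionRecording]:
    """Read every session CSV (with JSON sidecar) under a directory."""
    data_dir = Path(data_dir)
    paths = sorted(p for p in data_dir.glob("*.csv") if p.with_suffix(".json").exists())
    return [read_session(p) for p in paths]


def sessions_to_features(
    sessions: list[SessionRecording], config: RunConfig
) -> tuple[pd.DataFrame, list[dict]]:
    """Extract the WRI feature triple per session; failures go to a manifest."""
    m = config.metrics
    rows, failures = [], []
    for session in sessions:
        try:
            feats = extract_features(
                session,
                wrist_policy=m.wrist_policy,
                prominence_deg=m.prominence_deg,
                min_gap_s=m.min_gap_s,
                cutoff_hz=config.preprocess.cutoff_hz,
                order=config.preprocess.order,
            )
        except Exception as exc:  # noqa: BLE001 - logged and surfaced in manifest
            log.warning("session %s failed: %s", session.participant_id, exc)
            failures.append({"participant_id": session.participant_id, "error": str(exc)})
            continue
        rows.append(
            {
                "participant_id": session.participant_id,
                "group": session.group,
                "age_months": session.age_months,
                "trt_s": feats.trt,
                "roa_deg": feats.roa,
                "symmetry": feats.symmetry,
                "low_motion_flag": feats.low_motion,
            }
        )
    return build_cohort_table(rows), failures


def cohort_statistics(table: pd.DataFrame) -> dict:
    """ART ANOVA + ART-C post-hoc per metric, plus the group x age chi-square."""
    out: dict = {"anova": {}, "posthoc": {}}
    for col in METRIC_COLUMNS:
        res = art_anova_two_way(table, col)
        out["anova"][col] = res.effects
        out["posthoc"][col] = [asdict(r) for r in artc_posthoc(table, col, "group")]
    counts = (
        table.groupby(["age_band", "group"]).size().unstack(fill_value=0)
        .reindex(columns=["ASD", "TD"])
    )
    chi2, p, dof = chi_square_independence(counts.to_numpy())
    out["chi_square_group_by_age"] = {
        "chi2": chi2,
        "p": p,
        "df": dof,
        "table": counts.to_dict(),
    }
    return out


def run_pipeline(
    config: RunConfig,
    data_dir: str | Path | None,
    out_dir: str | Path,
    simulate: bool = False,
) -> dict:
    """Run the full analysis; writes features CSV, stats/benchmark JSON and a summary.

    With ``simulate=True`` a synthetic cohort is generated (and written under
    ``out_dir/sessions``) instead of reading ``data_dir``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": config.content_hash(), "seed": config.seed}
    log.info("pipeline start (config %s, seed %d)", stamp["config_hash"], config.seed)

    if simulate:
        n = config.simulate.n_per_cell
        sessions = simulate_cohort(
            n_per_cell=n if n is not None else STUDY_CELL_COUNTS, seed=config.seed
        )
        session_dir = out_dir / "sessions"
        for s in sessions:
            write_session(s, session_dir / f"{s.participant_id}.csv")
        log.info("simulated %d sessions -> %s", len(sessions), session_dir)
    else:
        if data_dir is None:
            raise ValueError("data_dir is required unless simulate=True")
        sessions = load_sessions(data_dir)
        if not sessions:
            raise FileNotFoundError(
                f"no session CSV/JSON pairs found under {data_dir}; "
                "pass simulate=True (CLI: --simulate) to generate a synthetic cohort"
            )

    table, failures = sessions_to_features(sessions, config)
    features_path = out_dir / "features.csv"
    table.assign(**stamp).to_csv(features_path, index=False)

    stats_report = {**stamp, **cohort_statistics(table)}
    (out_dir / "stats.json").write_text(json.dumps(stats_report, indent=1, default=str))

    c = config.classify
    bench = run_benchmark(
        table,
        seed=config.seed,
        test_frac=c.test_frac,
        n_repeats_cv=c.n_repeats_cv,
        n_repeat_splits=c.n_repeat_splits,
    )
    bench_json = {
        **stamp,
        "reports": [r.to_dict() for r in bench["reports"]],
        "repeated_splits": bench["repeated_splits"],
        "ranking": bench["ranking"],
    }
    (out_dir / "benchmark.json").write_text(json.dumps(bench_json, indent=1))

    if failures:
        (out_dir / "failures.json").write_text(json.dumps({**stamp, "failures": failures}, indent=1))

    summary = _summarise(table, stats_report, bench_json, stamp)
    (out_dir / "summary.txt").write_text(summary)
    log.info("pipeline done: %d participants, %d failures", len(table), len(failures))
    return {
        "features": table,
        "stats": stats_report,
        "benchmark": bench_json,
        "failures": failures,
        "summary": summary,
    }


def _summarise(table: pd.DataFrame, stats_report: dict, bench: dict, stamp: dict) -> str:
    lines = [
        f"WRI pipeline summary (config {stamp['config_hash']}, seed {stamp['seed']})",
        f"participants: {len(table)} "
        f"(ASD {(table['group'] == 'ASD').sum()}, TD {(table['group'] == 'TD').sum()})",
        "",
        "group means:",
    ]
    means = table.groupby("group")[["trt_s", "roa_deg", "symmetry"]].mean()
    lines.append(means.to_string(float_format=lambda v: f"{v:.3f}"))
    lines.append("")
    lines.append("ART ANOVA, population-type main effect:")
    for metric, effects in stats_report["anova"].items():
        e = effects["group"]
        lines.append(
            f"  {metric}: F({e['df1']},{e['df2']}) = {e['F']:.2f}, "
            f"p = {e['p']:.2e}, partial eta^2 = {e['partial_eta2']:.2f}"
        )
    lines.append("")
    lines.append("classifier held-out performance (single 10% split):")
    for r in bench["reports"]:
        lines.append(
            f"  {r['algorithm']}: acc {r['accuracy']:.2f}, auc {r['auc']:.2f}, "
            f"sens {r['sensitivity']:.2f}, spec {r['specificity']:.2f}"
        )
    lines.append(f"ranking: {' > '.join(bench['ranking'])}")
    return "\n".join(lines) + "\n"
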