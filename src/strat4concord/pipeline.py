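"""Orchestration: call -> score -> concordance as one configured run.

``run`` reads the three input CSVs (Ct panels, IHC observations, FISH
ratios), applies the call engine and the reference scoring rules, then emits
a concordance report with one row per configured analysis — by default the
eleven analyte x rule x stratum configurations of the standard validation
layout (ER and PR at 1%/10%, HER2 with FISH reflex / 2+ excluded / FISH
alone plus the two ER strata, Ki67 at 20%/10%).

Outputs in the run directory: ``calls.csv``, ``status.csv``,
``concordance.csv`` (+ ``.json`` machine twin and ``.txt`` human table),
``roc.csv``, and ``run.log`` reconciling input, analysed and excluded
counts.  Partial outputs are removed if the run fails.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import __version__
from .calls import ANALYTES, AssayConfig, call_table, read_panels
from .ihc import ComparatorRule, DEFAULT_RULES, read_fish, read_ihc, score_table
from .concordance import (
    ConcordanceReport,
    agreement_stats,
    build_table,
    roc,
    round_half_up,
)

__all__ = ["AnalysisSpec", "DEFAULT_ANALYSES", "RunConfig", "concordance_frame", "run"]


@dataclass(frozen=True)
class AnalysisSpec:
    """One report row: an analyte against one comparator rule, optionally
    restricted to a stratum defined by another rule's status."""

    analysis_id: str
    analyte: str
    rule_id: str
    stratum_rule_id: str | None = None
    stratum_status: str | None = None


DEFAULT_ANALYSES: tuple[AnalysisSpec, ...] = (
    AnalysisSpec("esr1_er_1pct", "ESR1", "er_1pct"),
    AnalysisSpec("esr1_er_10pct", "ESR1", "er_10pct"),
    AnalysisSpec("pgr_pr_1pct", "PGR", "pr_1pct"),
    AnalysisSpec("pgr_pr_10pct", "PGR", "pr_10pct"),
    AnalysisSpec("erbb2_ihc_plus_fish", "ERBB2", "her2_ihc_plus_fish"),
    AnalysisSpec("erbb2_ihc_excluding_2plus", "ERBB2", "her2_ihc_excluding_2plus"),
    AnalysisSpec("erbb2_fish_only", "ERBB2", "her2_fish_only"),
    AnalysisSpec("erbb2_ihc_plus_fish_er_pos", "ERBB2", "her2_ihc_plus_fish", "er_1pct", "POSITIVE"),
    AnalysisSpec("erbb2_ihc_plus_fish_er_neg", "ERBB2", "her2_ihc_plus_fish", "er_1pct", "NEGATIVE"),
    AnalysisSpec("mki67_ki67_20pct", "MKI67", "ki67_20pct"),
    AnalysisSpec("mki67_ki67_10pct", "MKI67", "ki67_10pct"),
)


def _fmt_prop(p) -> str:
    if not p.defined:
        return "undefined"
    lo, hi = p.ci_percent
    return f"{p.percent:.1f}% ({lo:.1f}-{hi:.1f}%)"


def _fmt_kappa(k) -> str:
    if not k.defined:
        return "undefined"
    return (
        f"{k.percent:.1f}% ({round_half_up(100 * k.lower):.1f}-"
        f"{round_half_up(100 * k.upper):.1f}%)"
    )


def concordance_frame(
    calls: pd.DataFrame,
    status: pd.DataFrame,
    analyses: Sequence[AnalysisSpec] = DEFAULT_ANALYSES,
    ci_method: str = "clopper_pearson",
) -> tuple[pd.DataFrame, dict[str, ConcordanceReport]]:
    """One concordance report row per analysis configuration.

    ``calls``: the call engine's long table; ``status``: the scored reference
    table.  Returns the tabular report and the full report objects keyed by
    analysis id.
    """
    rows = []
    reports: dict[str, ConcordanceReport] = {}
    for spec in analyses:
        sub_calls = calls[calls["analyte"] == spec.analyte].set_index("sample_id")["status"]
        ref = status[status["rule_id"] == spec.rule_id].set_index("sample_id")["status"]
        if spec.stratum_rule_id is not None:
            strat = status[status["rule_id"] == spec.stratum_rule_id].set_index("sample_id")["status"]
            keep = set(strat[strat == spec.stratum_status].index)
            sub_calls = sub_calls[sub_calls.index.isin(keep)]
            ref = ref[ref.index.isin(keep)]
        table = build_table(sub_calls, ref)
        if table.total == 0:
            rows.append({"analysis_id": spec.analysis_id, "analyte": spec.analyte,
                         "rule_id": spec.rule_id, "n": 0, "status": "UNDEFINED"})
            continue
        report = agreement_stats(
            table, ci_method=ci_method,
            configuration={"analysis_id": spec.analysis_id, "analyte": spec.analyte,
                           "rule_id": spec.rule_id,
                           "stratum": spec.stratum_status and f"{spec.stratum_rule_id}={spec.stratum_status}"},
        )
        reports[spec.analysis_id] = report
        excl = table.exclusion_counts()
        rows.append(
            {
                "analysis_id": spec.analysis_id,
                "analyte": spec.analyte,
                "rule_id": spec.rule_id,
                "stratum": (f"{spec.stratum_rule_id}={spec.stratum_status}"
                            if spec.stratum_rule_id else ""),
                "a": table.a, "b": table.b, "c": table.c, "d": table.d,
                "n": table.total,
                "n_excluded": table.n_excluded,
                "excluded_breakdown": ";".join(f"{k}={v}" for k, v in sorted(excl.items())),
                "ppa_pct": report.ppa.percent,
                "ppa_ci_low": report.ppa.ci_percent[0],
                "ppa_ci_high": report.ppa.ci_percent[1],
                "npa_pct": report.npa.percent,
                "npa_ci_low": report.npa.ci_percent[0],
                "npa_ci_high": report.npa.ci_percent[1],
                "kappa_pct": report.kappa.percent,
                "kappa_ci_low": round_half_up(100 * report.kappa.lower),
                "kappa_ci_high": round_half_up(100 * report.kappa.upper),
                "opa_pct": report.opa.percent,
                "opa_ci_low": report.opa.ci_percent[0],
                "opa_ci_high": report.opa.ci_percent[1],
            }
        )
    return pd.DataFrame(rows), reports


def _report_text(frame: pd.DataFrame, reports: dict[str, ConcordanceReport]) -> str:
    lines = [
        "Concordance of RT-qPCR calls with the reference method",
        "analysis | a/b/c/d (ref+/idx+, ref-/idx+, ref+/idx-, ref-/idx-) | n | "
        "PPA | NPA | kappa | OPA",
    ]
    for row in frame.itertuples():
        rep = reports.get(row.analysis_id)
        if rep is None:
            lines.append(f"{row.analysis_id}: no analysable samples")
            continue
        t = rep.table
        lines.append(
            f"{row.analysis_id} | {t.a}/{t.b}/{t.c}/{t.d} | {t.total} | "
            f"{_fmt_prop(rep.ppa)} | {_fmt_prop(rep.npa)} | "
            f"{_fmt_kappa(rep.kappa)} | {_fmt_prop(rep.opa)}"
        )
    return "\n".join(lines) + "\n"


def _report_json(reports: dict[str, ConcordanceReport]) -> dict:
    out = {}
    for aid, rep in reports.items():
        t = rep.table
        out[aid] = {
            "configuration": dict(rep.configuration),
            "counts": {"a": t.a, "b": t.b, "c": t.c, "d": t.d, "n": t.total},
            "excluded": t.exclusion_counts(),
            "ppa": {"estimate": rep.ppa.estimate, "ci": [rep.ppa.lower, rep.ppa.upper]},
            "npa": {"estimate": rep.npa.estimate, "ci": [rep.npa.lower, rep.npa.upper]},
            "opa": {"estimate": rep.opa.estimate, "ci": [rep.opa.lower, rep.opa.upper]},
            "kappa": {"estimate": rep.kappa.kappa, "se": rep.kappa.se,
                      "ci": [rep.kappa.lower, rep.kappa.upper]},
        }
    return out


PRIMARY_ROC_RULES = {
    "ESR1": "er_1pct",
    "PGR": "pr_1pct",
    "ERBB2": "her2_ihc_plus_fish",
    "MKI67": "ki67_20pct",
}


def roc_frame(calls: pd.DataFrame, status: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, float]]:
    """ROC points (and AUC) of each analyte's dCt against its primary rule."""
    import numpy as np

    rows = []
    aucs: dict[str, float] = {}
    for analyte, rule_id in PRIMARY_ROC_RULES.items():
        sub = calls[(calls["analyte"] == analyte) & (calls["status"] != "INVALID")]
        sub = sub[np.isfinite(sub["dct"].to_numpy(float))]
        ref = status[status["rule_id"] == rule_id]
        ref = ref[ref["status"].isin(["POSITIVE", "NEGATIVE", "HIGH", "LOW"])]
        merged = sub.merge(ref[["sample_id", "status"]], on="sample_id", suffixes=("", "_ref"))
        if merged.empty:
            aucs[analyte] = math.nan
            continue
        labels = merged["status_ref"].isin(["POSITIVE", "HIGH"]).to_numpy()
        result = roc(merged["dct"].to_numpy(float), labels)
        aucs[analyte] = result.auc
        for thr, fpr, tpr in zip(result.thresholds, result.fpr, result.tpr):
            rows.append({"analyte": analyte, "threshold": thr, "fpr": fpr, "tpr": tpr})
    return pd.DataFrame(rows), aucs


@dataclass
class RunConfig:
    """Paths, assay configuration and analysis set for one pipeline run."""

    panels: str | Path
    ihc: str | Path
    fish: str | Path | None
    outdir: str | Path
    assay: AssayConfig = field(default_factory=AssayConfig)
    rules: Sequence[ComparatorRule] = DEFAULT_RULES
    analyses: Sequence[AnalysisSpec] = DEFAULT_ANALYSES
    ci_method: str = "clopper_pearson"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            d = yaml.safe_load(fh)
        base = path.parent

        def resolve(p):
            return None if p is None else (base / p if not Path(p).is_absolute() else Path(p))

        kwargs = dict(
            panels=resolve(d["panels"]),
            ihc=resolve(d["ihc"]),
            fish=resolve(d.get("fish")),
            outdir=resolve(d["outdir"]),
        )
        if "assay" in d:
            kwargs["assay"] = AssayConfig.from_dict(d["assay"])
        if "rules" in d:
            kwargs["rules"] = tuple(ComparatorRule.from_dict(r) for r in d["rules"])
        if "analyses" in d:
            kwargs["analyses"] = tuple(
                AnalysisSpec(
                    a["analysis_id"], a["analyte"], a["rule_id"],
                    a.get("stratum_rule_id"), a.get("stratum_status"),
                )
                for a in d["analyses"]
            )
        if "ci_method" in d:
            kwargs["ci_method"] = d["ci_method"]
        return cls(**kwargs)


def run(config: RunConfig) -> dict[str, Path]:
    """Execute the full pipeline; returns the paths of the written outputs."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def out(name: str) -> Path:
        p = outdir / name
        written.append(p)
        return p

    try:
        panels = read_panels(config.panels)
        ihc = read_ihc(config.ihc)
        fish = read_fish(config.fish) if config.fish else None

        calls = call_table(panels, config.assay)
        calls.to_csv(out("calls.csv"), index=False, float_format="%.6g")

        status = score_table(ihc, fish, config.rules)
        status.to_csv(out("status.csv"), index=False, float_format="%.6g")

        frame, reports = concordance_frame(calls, status, config.analyses, config.ci_method)
        frame.to_csv(out("concordance.csv"), index=False)
        out("concordance.json").write_text(json.dumps(_report_json(reports), indent=2))
        out("concordance.txt").write_text(_report_text(frame, reports))

        roc_points, aucs = roc_frame(calls, status)
        roc_points.to_csv(out("roc.csv"), index=False, float_format="%.6g")

        log_lines = [
            f"strat4concord {__version__}",
            f"panels: {config.panels} ({len(panels)} samples)",
            f"ihc: {config.ihc} ({len(ihc)} observations)",
            f"fish: {config.fish}",
            f"ci_method: {config.ci_method}",
            f"assay: {config.assay.to_dict()}",
            "auc: " + ", ".join(f"{k}={v:.4f}" for k, v in aucs.items()),
        ]
        for aid, rep in reports.items():
            t = rep.table
            log_lines.append(
                f"{aid}: n_input={t.total + t.n_excluded} analysed={t.total} "
                f"excluded={t.n_excluded} {t.exclusion_counts()}"
            )
        out("run.log").write_text("\n".join(log_lines) + "\n")
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise
    return {p.stem: p for p in written}
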