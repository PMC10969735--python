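"""End-to-end analysis orchestration.

Runs the full statistical plan over a cohort index table and PBS totals
and emits three result surfaces:

1. per-marker index comparison — Friedman omnibus over the four sensory
   indexes, Conover post hoc on all six index pairs (gated on omnibus
   significance), and median/IQR descriptives;
2. cross-marker agreement — Spearman correlation between each index
   computed at the lateral malleolus and at the mastoid process;
3. PBS summary (mean, sd) and Spearman correlations of PBS totals with
   every index at both markers.

The report is deterministic given the inputs and configuration: it
carries a configuration hash but no timestamps, so repeated runs are
byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .conditions import ALL_MARKERS, Marker
from .errors import DegenerateProfileError, InputError
from .indexes import INDEX_NAMES, build_cohort_index_table
from .pbs import read_pbs_csv
from .stats import (
    BlockMatrix,
    conover_posthoc,
    friedman_test,
    spearman_correlation,
    summarize_median_iqr,
)

logger = logging.getLogger(__name__)

INDEX_LABELS = {"som": "Somatosensory", "vis": "Visual", "vest": "Vestibular", "vp": "Visual preference"}


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable analysis parameters (loadable from YAML/JSON)."""

    sway_method: str = "path_length"
    index_scale: str = "ratio"
    window_s: float = 20.0
    cm_per_pixel: float | None = None
    allow_single_trial: bool = False
    denom_epsilon: float = 1e-9
    alpha: float = 0.05
    posthoc_adjust: str = "none"
    always_posthoc: bool = False

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise InputError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _marker_section(idx: pd.DataFrame, marker: Marker, cfg: AnalysisConfig) -> dict[str, Any] | None:
    sub = idx[idx["marker"] == marker.value].sort_values("participant_id")
    n = len(sub)
    if n < 2:
        logger.error("marker %s: only %d complete participant(s); analysis aborted", marker.value, n)
        return None
    m = BlockMatrix(
        values=sub[list(INDEX_NAMES)].to_numpy(dtype=float),
        block_labels=tuple(sub["participant_id"]),
        treatment_labels=INDEX_NAMES,
    )
    omnibus = friedman_test(m)
    descr = {
        name: dict(zip(("median", "iqr"), summarize_median_iqr(sub[name].to_numpy())))
        for name in INDEX_NAMES
    }
    posthoc: list[dict[str, Any]] = []
    if omnibus.p_value < cfg.alpha or cfg.always_posthoc:
        try:
            posthoc = [dataclasses.asdict(p) for p in conover_posthoc(m, adjust=cfg.posthoc_adjust)]
        except DegenerateProfileError as exc:
            logger.warning("marker %s: post hoc skipped (%s)", marker.value, exc)
    return {
        "n": n,
        "friedman": dataclasses.asdict(omnibus),
        "descriptives": descr,
        "posthoc": posthoc,
    }


def analyze_tables(
    index_table: pd.DataFrame,
    pbs_table: pd.DataFrame,
    cfg: AnalysisConfig | None = None,
) -> dict[str, Any]:
    """Run the statistical plan over in-memory tables.

    ``index_table`` needs columns ``participant_id, marker, som, vis,
    vest, vp``; ``pbs_table`` needs ``participant_id, pbs_total``.
    Returns the report as a JSON-serializable dict.
    """
    cfg = cfg or AnalysisConfig()
    if len(index_table) == 0:
        raise InputError("empty index table")
    report: dict[str, Any] = {
        "provenance": {
            "software": "ctsib-sway",
            "version": __version__,
            "config_hash": cfg.hash(),
            "config": dataclasses.asdict(cfg),
        },
        "markers": {},
    }
    for marker in ALL_MARKERS:
        section = _marker_section(index_table, marker, cfg)
        if section is not None:
            report["markers"][marker.value] = section

    # cross-marker agreement on participants complete at both markers
    agreement: dict[str, Any] = {}
    wide = index_table.pivot_table(
        index="participant_id", columns="marker", values=list(INDEX_NAMES), aggfunc="first"
    ).dropna()
    if len(wide) >= 3:
        for name in INDEX_NAMES:
            res = spearman_correlation(
                wide[(name, Marker.LATERAL_MALLEOLUS.value)].to_numpy(),
                wide[(name, Marker.MASTOID_PROCESS.value)].to_numpy(),
            )
            agreement[name] = dataclasses.asdict(res)
    else:
        logger.error("fewer than 3 participants complete at both markers; agreement skipped")
    report["cross_marker_agreement"] = agreement

    pbs = pbs_table.dropna(subset=["pbs_total"])
    totals = pbs["pbs_total"].to_numpy(dtype=float)
    report["pbs"] = {
        "n": int(totals.size),
        "mean": float(totals.mean()) if totals.size else float("nan"),
        "sd": float(totals.std(ddof=1)) if totals.size > 1 else float("nan"),
    }

    pbs_corr: dict[str, Any] = {}
    for marker in ALL_MARKERS:
        sub = index_table[index_table["marker"] == marker.value]
        merged = sub.merge(pbs, on="participant_id", how="inner")
        if len(merged) < 3:
            continue
        pbs_corr[marker.value] = {
            name: dataclasses.asdict(
                spearman_correlation(merged[name].to_numpy(), merged["pbs_total"].to_numpy())
            )
            for name in INDEX_NAMES
        }
    report["pbs_correlations"] = pbs_corr
    return report


def run_analysis(
    manifest_path: str | Path,
    pbs_path: str | Path,
    cfg: AnalysisConfig | None = None,
    out_dir: str | Path | None = None,
) -> dict[str, Any]:
    """File-based entry point: manifest + trace CSVs + PBS CSV → report.

    When ``out_dir`` is given, writes ``report.json``, the two table
    twins (``table2_indexes.csv``, ``table3_agreement.csv``) and a
    plain-text ``summary.txt``.
    """
    cfg = cfg or AnalysisConfig()
    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path)
    index_table = build_cohort_index_table(
        manifest,
        base_dir=manifest_path.parent,
        method=cfg.sway_method,  # type: ignore[arg-type]
        scale=cfg.index_scale,  # type: ignore[arg-type]
        window_s=cfg.window_s,
        cm_per_pixel=cfg.cm_per_pixel,
        allow_single_trial=cfg.allow_single_trial,
        denom_epsilon=cfg.denom_epsilon,
    )
    pbs_table = read_pbs_csv(pbs_path)
    report = analyze_tables(index_table, pbs_table, cfg)
    if out_dir is not None:
        write_report(report, out_dir)
    return report


def render_tables(report: dict[str, Any]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Render the report into the two publication-shaped tables.

    Table-2 twin: per marker, four index rows (median, IQR) followed by
    the pairwise comparison rows (empty when the omnibus was not
    significant). Table-3 twin: one cross-marker agreement row per
    index.
    """
    t2_rows: list[dict[str, Any]] = []
    for marker, section in report["markers"].items():
        for name in INDEX_NAMES:
            d = section["descriptives"][name]
            t2_rows.append(
                {
                    "marker": marker,
                    "index": INDEX_LABELS[name],
                    "median": d["median"],
                    "iqr": d["iqr"],
                    "comparison": "",
                    "statistic": np.nan,
                    "p": np.nan,
                }
            )
        for pair in section["posthoc"]:
            t2_rows.append(
                {
                    "marker": marker,
                    "index": "",
                    "median": np.nan,
                    "iqr": np.nan,
                    "comparison": f"{pair['treatment_a']}-{pair['treatment_b']}",
                    "statistic": pair["statistic"],
                    "p": pair["p_unadjusted"],
                }
            )
    table2 = pd.DataFrame(t2_rows, columns=["marker", "index", "median", "iqr", "comparison", "statistic", "p"])
    t3_rows = [
        {"index": INDEX_LABELS[name], "rho": res["rho"], "p": res["p_value"]}
        for name, res in report["cross_marker_agreement"].items()
    ]
    table3 = pd.DataFrame(t3_rows, columns=["index", "rho", "p"])
    return table2, table3


def summarize_report(report: dict[str, Any]) -> str:
    """Human-readable plain-text summary of the report."""
    lines = ["m-CTSIB sensory participation analysis", "=" * 38]
    for marker, sec in report["markers"].items():
        fr = sec["friedman"]
        lines.append(
            f"\n{marker} (n={sec['n']}): Friedman X2={fr['statistic']:.2f}, "
            f"df={fr['df']}, p={fr['p_value']:.3g}"
        )
        for name in INDEX_NAMES:
            d = sec["descriptives"][name]
            lines.append(f"  {INDEX_LABELS[name]:<18} Md={d['median']:.2f}  IQR={d['iqr']:.2f}")
        if sec["posthoc"]:
            for pair in sec["posthoc"]:
                lines.append(
                    f"  {pair['treatment_a']}-{pair['treatment_b']}: "
                    f"t={pair['statistic']:.2f}, p={pair['p_unadjusted']:.3g}"
                )
        else:
            lines.append("  (omnibus not significant; post hoc omitted)")
    if report["cross_marker_agreement"]:
        lines.append("\nCross-marker agreement (malleolus vs mastoid):")
        for name, res in report["cross_marker_agreement"].items():
            lines.append(f"  {INDEX_LABELS[name]:<18} rho={res['rho']:.3f}, p={res['p_value']:.3g}")
    pbs = report["pbs"]
    lines.append(f"\nPBS total: mean={pbs['mean']:.2f}, sd={pbs['sd']:.2f} (n={pbs['n']})")
    for marker, corr in report.get("pbs_correlations", {}).items():
        for name, res in corr.items():
            lines.append(
                f"  PBS vs {INDEX_LABELS[name]:<18} ({marker}): "
                f"rho={res['rho']:.3f}, p={res['p_value']:.3g}"
            )
    return "\n".join(lines) + "\n"


def write_report(report: dict[str, Any], out_dir: str | Path) -> Path:
    """Write report.json, the table twins and summary.txt into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    table2, table3 = render_tables(report)
    table2.to_csv(out / "table2_indexes.csv", index=False, float_format="%.6g")
    table3.to_csv(out / "table3_agreement.csv", index=False, float_format="%.6g")
    (out / "summary.txt").write_text(summarize_report(report))
    return out
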