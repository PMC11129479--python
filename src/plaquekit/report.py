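"""Group-comparison report assembly.

Bundles per-metric group summaries (mean ± SD, n), a normality screen,
one-way ANOVA and Holm–Šidák-adjusted pairwise comparisons into DataFrames
plus a JSON-serializable dict.  The Holm–Šidák family is the set of pairwise
contrasts within one metric, not across metrics.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import GroupTable, dagostino_pearson, holm_sidak, one_way_anova, pearson_corr

__all__ = ["ReportBundle", "group_report", "write_report"]


@dataclass
class ReportBundle:
    summary: pd.DataFrame
    anova: pd.DataFrame
    pairwise: pd.DataFrame
    correlations: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "meta": self.meta,
            "summary": self.summary.to_dict(orient="records"),
            "anova": self.anova.to_dict(orient="records"),
            "pairwise": self.pairwise.to_dict(orient="records"),
            "correlations": self.correlations.to_dict(orient="records"),
        }


def _pairwise_welch(a, b) -> tuple[float, float]:
    res = sps.ttest_ind(np.asarray(a, float), np.asarray(b, float), equal_var=False)
    return float(res.statistic), float(res.pvalue)


def group_report(
    tables: list[GroupTable],
    alpha: float = 0.05,
    correlation_pairs: list[tuple[str, str]] | None = None,
    unit_of_analysis: str = "animal",
) -> ReportBundle:
    """Assemble the statistical report for a set of metric tables.

    Single-group metrics get summaries only, with tests skipped and noted.
    ``correlation_pairs`` names metric pairs to correlate; the metrics must
    share group labels and per-group sample counts.
    """
    if not tables:
        raise ValueError("no metric tables given")
    by_name = {t.name: t for t in tables}
    summary_rows, anova_rows, pairwise_rows, corr_rows = [], [], [], []

    for t in tables:
        for g, xs in t.groups.items():
            xs = np.asarray(xs, float)
            row = {
                "metric": t.name,
                "group": g,
                "n": xs.size,
                "mean": xs.mean() if xs.size else np.nan,
                "sd": xs.std(ddof=1) if xs.size > 1 else np.nan,
                "units": t.units,
            }
            if xs.size >= 20:
                norm = dagostino_pearson(xs)
                row["normality_p"] = norm.p_value
            else:
                row["normality_p"] = np.nan
            summary_rows.append(row)

        if len(t.groups) < 2:
            anova_rows.append(
                {"metric": t.name, "F": np.nan, "df1": np.nan, "df2": np.nan,
                 "p": np.nan, "note": "single group: tests skipped"}
            )
            continue
        res = one_way_anova(t)
        anova_rows.append(
            {"metric": t.name, "F": res.statistic, "df1": res.df[0],
             "df2": res.df[1], "p": res.p_value, "note": res.note}
        )
        pairs = list(itertools.combinations(t.labels, 2))
        raw = []
        for ga, gb in pairs:
            stat, p = _pairwise_welch(t.groups[ga], t.groups[gb])
            raw.append((ga, gb, stat, p))
        adjusted = holm_sidak([p for *_, p in raw])
        for (ga, gb, stat, p), adj in zip(raw, adjusted):
            pairwise_rows.append(
                {"metric": t.name, "group_a": ga, "group_b": gb, "t": stat,
                 "p_raw": p, "p_adjusted": adj, "significant": adj <= alpha}
            )

    for a_name, b_name in correlation_pairs or []:
        ta, tb = by_name[a_name], by_name[b_name]
        for g in ta.labels:
            if g not in tb.groups:
                continue
            xs, ys = ta.groups[g], tb.groups[g]
            if len(xs) != len(ys) or len(xs) < 3:
                continue
            try:
                res = pearson_corr(xs, ys)
            except ValueError:
                continue
            corr_rows.append(
                {"metric_x": a_name, "metric_y": b_name, "group": g,
                 "n": len(xs), "r": res.statistic, "p": res.p_value}
            )

    return ReportBundle(
        summary=pd.DataFrame(summary_rows),
        anova=pd.DataFrame(anova_rows),
        pairwise=pd.DataFrame(pairwise_rows),
        correlations=pd.DataFrame(corr_rows),
        meta={"alpha": alpha, "unit_of_analysis": unit_of_analysis,
              "pairwise_family": "within-metric", "test": "welch_t + holm_sidak"},
    )


def write_report(bundle: ReportBundle, outdir) -> None:
    """Emit summary/anova/pairwise CSVs and the full report JSON."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.summary.to_csv(out / "summary.csv", index=False)
    bundle.anova.to_csv(out / "anova.csv", index=False)
    bundle.pairwise.to_csv(out / "pairwise.csv", index=False)
    if len(bundle.correlations):
        bundle.correlations.to_csv(out / "correlations.csv", index=False)
    with open(out / "report.json", "w") as fh:
        json.dump(bundle.to_dict(), fh, indent=2, default=float)
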