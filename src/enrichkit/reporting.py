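"""Tabular report bundles tying the pipeline stages together.

Reports are emitted twice from the same numbers: human-readable text with
values rounded to two decimals, and machine-readable TSV at full precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from .metrics import Significance, classify_significance, delta_proc_prep, summarize_delta_table
from .normalization import NormalizationReport


@dataclass
class ReportBundle:
    """A summary table plus optional per-class counts and figure paths."""

    table: pd.DataFrame
    counts: dict = field(default_factory=dict)
    figures: dict = field(default_factory=dict)
    title: str = ""

    def counts_line(self) -> str:
        if not self.counts:
            return ""
        return (
            f"{self.counts.get(Significance.FAVORS_FIRST.value, 0)} favor first / "
            f"{self.counts.get(Significance.FAVORS_SECOND.value, 0)} favor second / "
            f"{self.counts.get(Significance.NON_SIGNIFICANT.value, 0)} non-significant"
        )

    def to_text(self) -> str:
        df = self.table.copy()
        for col in df.columns:
            if pd.api.types.is_float_dtype(df[col]):
                df[col] = df[col].map(lambda v: f"{v:.2f}")
        lines = []
        if self.title:
            lines.append(self.title)
        lines.append(df.to_string(index=False))
        if self.counts:
            lines.append(self.counts_line())
        return "\n".join(lines)

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        self.table.to_csv(path, sep="\t", index=False)
        return path


def compare_preps_report(
    aucs: Mapping[str, tuple],
    margin: float = 0.05,
    first_label: str = "first",
    second_label: str = "second",
) -> ReportBundle:
    """Per-target preparation comparison: AUC pair, delta, significance mark,
    plus the class-count summary line.

    ``aucs`` maps target name -> (auc_first, auc_second).
    """
    rows = []
    deltas = {}
    for target, (a_first, a_second) in aucs.items():
        delta = delta_proc_prep(a_first, a_second)
        deltas[target] = delta
        cls = classify_significance(delta, margin)
        rows.append(
            {
                "target": target,
                f"auc_{first_label}": float(a_first),
                f"auc_{second_label}": float(a_second),
                "delta_prep": delta,
                "significance": cls.label.value,
            }
        )
    counts = summarize_delta_table(deltas, margin)
    return ReportBundle(
        table=pd.DataFrame(rows),
        counts=counts,
        title=f"Preparation comparison ({first_label} vs {second_label}), margin ±{margin:g}",
    )


def normalization_report_table(
    reports: Mapping[str, NormalizationReport], margin: float = 0.05
) -> ReportBundle:
    """Per-target normalization summary: original and normalized AUC, the
    normalization delta, bioactive-set mean NHA and the guideline flag."""
    rows = []
    deltas = {}
    for target, rep in reports.items():
        deltas[target] = rep.delta_n
        rows.append(
            {
                "target": target,
                "mode": rep.mode.label,
                "auc_original": rep.auc_original,
                "auc_normalized": rep.auc_normalized,
                "delta_n": rep.delta_n,
                "mean_nha": rep.mean_nha,
                "significance": classify_significance(rep.delta_n, margin).label.value,
                "recommendation": rep.recommendation.value,
            }
        )
    counts = summarize_delta_table(deltas, margin)
    return ReportBundle(
        table=pd.DataFrame(rows),
        counts=counts,
        title=f"Score normalization summary, margin ±{margin:g}",
    )
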