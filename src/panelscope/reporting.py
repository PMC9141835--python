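"""Report rendering: TSV, markdown and JSON writers for the summary surfaces.

Every percentage cell in the TSV output sits next to its raw numerator and
denominator so numbers are auditable; the markdown rendering mirrors the
"n (pct%)" cell style of clinical concordance tables for visual diffing.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from panelscope.cohort_io import CohortTable
from panelscope.coverage import (
    GeneCoverageSummary,
    MatchResult,
    disease_concordance,
    sample_level_summary,
    tier_stratified_summary,
    variant_level_summary,
)

__all__ = ["write_reports", "render_sample_table_md", "render_concordance_md"]


def _gene_summary_frame(summaries: dict[str, GeneCoverageSummary]) -> pd.DataFrame:
    rows = [
        {
            "gene": s.gene,
            "n_records": s.n_records,
            "n_detectable": s.n_detectable,
            "pct_detectable": s.pct_detectable,
        }
        for s in summaries.values()
    ]
    return pd.DataFrame(rows, columns=["gene", "n_records", "n_detectable", "pct_detectable"])


def _diagnosis_frame(summaries: dict[str, GeneCoverageSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries.values():
        for diagnosis, n in sorted(s.by_diagnosis.items()):
            rows.append({"gene": s.gene, "diagnosis": diagnosis, "n_records": n})
    return pd.DataFrame(rows, columns=["gene", "diagnosis", "n_records"])


def render_sample_table_md(per_gene: pd.DataFrame) -> str:
    """Sample-level positives as a markdown table with 'n (pct%)' cells."""
    lines = ["| Gene | Idylla Positive | Idylla Negative |", "| --- | --- | --- |"]
    for _, row in per_gene.iterrows():
        lines.append(
            f"| *{row['gene']}* | {row['n_positive']} ({row['pct_positive']}) "
            f"| {row['n_negative']} ({row['pct_negative']}) |"
        )
    return "\n".join(lines) + "\n"


def render_concordance_md(conc: pd.DataFrame) -> str:
    lines = [
        "| Gene Mutation and Diagnosis | Case Numbers | Idylla Positive | Idylla Negative "
        "| Cases with Extra Mutations | Cases with Extra and High-Tier Mutations "
        "Not Detected |",
        "| --- | --- | --- | --- | --- | --- |",
    ]
    for _, row in conc.iterrows():
        def cell(n_col: str, pct_col: str) -> str:
            pct = row[pct_col]
            return f"{row[n_col]} ({pct})" if pct else str(row[n_col])
        lines.append(
            f"| *{row['gene']}* {row['diagnosis']} | {row['n_cases']} "
            f"| {cell('n_idylla_positive', 'pct_positive')} "
            f"| {cell('n_idylla_negative', 'pct_negative')} "
            f"| {cell('n_extra', 'pct_extra')} "
            f"| {cell('n_extra_high_tier', 'pct_extra_high_tier')} |"
        )
    return "\n".join(lines) + "\n"


def write_reports(
    outdir: str | Path,
    table: CohortTable,
    results: list[MatchResult],
    pairs: list[tuple[str, str]] | None = None,
    decimals: int = 1,
    high_tiers: tuple[str, ...] = ("1", "2"),
) -> dict:
    """Write all summary surfaces under ``outdir``; returns the JSON report dict.

    Files: gene_summary.tsv, tier_summary.tsv, diagnosis_summary.tsv,
    sample_summary.tsv, sample_table.{tsv,md}, concordance.{tsv,md} (when
    pairs given), report.json (everything plus provenance).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    summaries = variant_level_summary(results, decimals=decimals)
    gene_df = _gene_summary_frame(summaries)
    tier_df = tier_stratified_summary(results)
    diag_df = _diagnosis_frame(summaries)
    samples, per_gene = sample_level_summary(results, high_tiers=high_tiers)
    sample_df = pd.DataFrame(
        [
            {
                "sample_key": s.sample_key,
                "any_detectable": int(s.any_detectable),
                "n_panel_matches": s.n_panel_matches,
                "n_nonpanel": s.n_nonpanel,
                "has_extra_mutation": int(s.has_extra_mutation),
                "has_extra_high_tier_undetected": int(s.has_extra_high_tier_undetected),
            }
            for s in samples.values()
        ]
    )

    kwargs = {"sep": "\t", "index": False, "lineterminator": "\n", "encoding": "utf-8"}
    gene_df.to_csv(outdir / "gene_summary.tsv", **kwargs)
    tier_df.to_csv(outdir / "tier_summary.tsv", **kwargs)
    diag_df.to_csv(outdir / "diagnosis_summary.tsv", **kwargs)
    sample_df.to_csv(outdir / "sample_summary.tsv", **kwargs)
    per_gene.to_csv(outdir / "sample_table.tsv", **kwargs)
    (outdir / "sample_table.md").write_text(render_sample_table_md(per_gene), encoding="utf-8")

    report = {
        "provenance": [list(step) for step in table.provenance],
        "gene_summary": gene_df.to_dict(orient="records"),
        "tier_summary": tier_df.to_dict(orient="records"),
        "diagnosis_summary": diag_df.to_dict(orient="records"),
        "sample_table": per_gene.to_dict(orient="records"),
        "n_records": len(results),
        "n_matched": sum(1 for r in results if r.matched),
    }
    if pairs:
        conc = disease_concordance(results, pairs, high_tiers=high_tiers)
        conc.to_csv(outdir / "concordance.tsv", **kwargs)
        (outdir / "concordance.md").write_text(render_concordance_md(conc), encoding="utf-8")
        report["concordance"] = conc.to_dict(orient="records")
    (outdir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return report
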