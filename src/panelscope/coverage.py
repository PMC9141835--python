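"""Panel-coverage analysis: per-record matching and the summary surfaces.

Given a cohort table and a panel definition, every record is classified as
panel-detectable or not, and four summary surfaces are derived:

* variant-level per gene — what fraction of observed mutations the assay
  covers, with tier and primary-site breakdowns;
* tier-stratified per gene — coverage within each clinical-significance tier
  (AMP/ASCO/CAP: Tier 1/2 actionable, Tier 3 unknown, Tier 4 benign);
* unique-sample level — each study‖sample counted once, so a specimen with
  two detectable mutations is one positive, not two;
* disease concordance — per (gene, diagnosis) pair, case-level positivity
  plus the co-occurring "extra mutation" columns: cases carrying additional
  mutations beyond the index one, and cases where a high-tier mutation would
  have gone undetected by the panel.

Matching per record follows the representation precedence of
:func:`panelscope.hgvs_core.same_variant`: the protein level decides when both
sides carry it, the cDNA level otherwise; a record sharing no representation
level with any panel entry of its gene is indeterminate and counted
not-detectable with that reason recorded.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from panelscope.cohort_io import CohortRecord, CohortTable, TIERS
from panelscope.hgvs_core import VariantDescriptor, canonical_key
from panelscope.panel_registry import PanelDefinition, PanelVariant

__all__ = [
    "MatchResult",
    "GeneCoverageSummary",
    "SampleCoverageSummary",
    "UndefinedPercentError",
    "classify",
    "match_descriptor",
    "variant_level_summary",
    "tier_stratified_summary",
    "sample_level_summary",
    "disease_concordance",
    "format_percent",
    "HIGH_TIERS_DEFAULT",
]

HIGH_TIERS_DEFAULT = ("1", "2")


class UndefinedPercentError(ZeroDivisionError):
    """A percentage was requested with denominator zero."""


def format_percent(numerator: int, denominator: int, decimals: int = 0) -> str:
    """Render ``numerator/denominator`` as a percentage string.

    Rounding is round-half-up at the stated precision (0 or 1 decimals) —
    the convention clinical summary tables use, not banker's rounding.
    A zero denominator raises :class:`UndefinedPercentError`; callers
    suppress the row rather than print a 0/0 artifact.
    """
    if decimals not in (0, 1):
        raise ValueError("decimals must be 0 or 1")
    if denominator == 0:
        raise UndefinedPercentError(f"percentage of {numerator}/0 is undefined")
    quantum = Decimal("1") if decimals == 0 else Decimal("0.1")
    pct = (Decimal(numerator) * 100 / Decimal(denominator)).quantize(
        quantum, rounding=ROUND_HALF_UP
    )
    return f"{pct}%"


@dataclass(frozen=True)
class MatchResult:
    """Verdict of panel matching for one cohort record."""

    record: CohortRecord
    matched: bool
    matched_panel_variant: PanelVariant | None = None
    match_level: str | None = None  # "protein" | "cdna"
    reason: str = ""

    def __post_init__(self) -> None:
        if self.matched and (self.matched_panel_variant is None or self.match_level is None):
            raise ValueError("matched result requires panel variant and level")
        if not self.matched and not self.reason:
            raise ValueError("unmatched result requires a reason")


def _keys_of(descriptor: VariantDescriptor) -> tuple[str | None, str | None]:
    p = (
        canonical_key(descriptor, "protein").key_text
        if descriptor.protein is not None
        else None
    )
    c = (
        canonical_key(descriptor, "cdna").key_text
        if descriptor.cdna is not None
        else None
    )
    return p, c


class _PanelIndex:
    """Per-gene ordered (variant, protein key, cdna key) lists for fast matching."""

    def __init__(self, panel: PanelDefinition) -> None:
        self.by_gene: dict[str, list[tuple[PanelVariant, str | None, str | None]]] = {}
        for v in panel.variants:
            self.by_gene.setdefault(v.gene, []).append((v, *_keys_of(v.descriptor)))

    def match(self, descriptor: VariantDescriptor) -> tuple[PanelVariant | None, str | None, str]:
        """First matching panel variant in file order, its level, and a reason."""
        entries = self.by_gene.get(descriptor.gene)
        if not entries:
            return None, None, "gene not on panel"
        p_key, c_key = _keys_of(descriptor)
        any_comparable = False
        for variant, vp, vc in entries:
            if p_key is not None and vp is not None:
                any_comparable = True
                if p_key == vp:
                    return variant, "protein", ""
                continue  # protein level is decisive for this entry
            if c_key is not None and vc is not None:
                any_comparable = True
                if c_key == vc:
                    return variant, "cdna", ""
        return None, None, ("key not in panel" if any_comparable else "no shared representation")


def match_descriptor(descriptor: VariantDescriptor, panel: PanelDefinition,
                     record: CohortRecord | None = None) -> MatchResult:
    """Match a single descriptor against a panel."""
    if record is None:
        record = CohortRecord(
            study_id="-", sample_id="-", gene=descriptor.gene, descriptor=descriptor
        )
    variant, level, reason = _PanelIndex(panel).match(descriptor)
    if variant is None:
        return MatchResult(record, False, reason=reason)
    return MatchResult(record, True, matched_panel_variant=variant, match_level=level)


def classify(table: CohortTable, panel: PanelDefinition) -> list[MatchResult]:
    """One MatchResult per record, in table order.

    Records whose names failed the grammar are reported unmatched with
    reason "unparsable variant name" rather than dropped.
    """
    index = _PanelIndex(panel)
    results: list[MatchResult] = []
    for record in table.records:
        if record.descriptor is None:
            results.append(MatchResult(record, False, reason="unparsable variant name"))
            continue
        variant, level, reason = index.match(record.descriptor)
        if variant is None:
            results.append(MatchResult(record, False, reason=reason))
        else:
            results.append(
                MatchResult(record, True, matched_panel_variant=variant, match_level=level)
            )
    return results


@dataclass(frozen=True)
class GeneCoverageSummary:
    """Variant-level coverage for one gene, with tier and diagnosis breakdowns."""

    gene: str
    n_records: int
    n_detectable: int
    pct_detectable: str  # formatted per format_percent
    by_tier: dict  # tier -> (n, n_detectable)
    by_diagnosis: dict  # diagnosis -> n_records ("unspecified" pools absent)

    def __post_init__(self) -> None:
        if self.n_detectable > self.n_records:
            raise ValueError("n_detectable exceeds n_records")
        if sum(n for n, _ in self.by_tier.values()) != self.n_records:
            raise ValueError("tier strata do not partition records")
        if sum(self.by_diagnosis.values()) != self.n_records:
            raise ValueError("diagnosis strata do not partition records")


def variant_level_summary(results: list[MatchResult],
                          decimals: int = 1) -> dict[str, GeneCoverageSummary]:
    """Per-gene record counts and detectable fractions.

    Genes with zero records are simply absent (never a 0/0 row).
    """
    per_gene: dict[str, list[MatchResult]] = {}
    for r in results:
        per_gene.setdefault(r.record.gene, []).append(r)
    out: dict[str, GeneCoverageSummary] = {}
    for gene in sorted(per_gene):
        rs = per_gene[gene]
        n = len(rs)
        n_det = sum(1 for r in rs if r.matched)
        by_tier: dict[str, tuple[int, int]] = {}
        for tier in TIERS:
            in_tier = [r for r in rs if r.record.tier == tier]
            if in_tier:
                by_tier[tier] = (len(in_tier), sum(1 for r in in_tier if r.matched))
        by_diag: dict[str, int] = {}
        for r in rs:
            d = r.record.diagnosis or "unspecified"
            by_diag[d] = by_diag.get(d, 0) + 1
        out[gene] = GeneCoverageSummary(
            gene=gene,
            n_records=n,
            n_detectable=n_det,
            pct_detectable=format_percent(n_det, n, decimals),
            by_tier=by_tier,
            by_diagnosis=by_diag,
        )
    return out


def tier_stratified_summary(results: list[MatchResult], decimals: int = 0) -> pd.DataFrame:
    """Per-gene, per-tier counts: columns gene, tier, n, n_detectable, pct_detectable."""
    summaries = variant_level_summary(results)
    rows = []
    for gene, s in summaries.items():
        for tier, (n, n_det) in s.by_tier.items():
            rows.append(
                {
                    "gene": gene,
                    "tier": tier,
                    "n": n,
                    "n_detectable": n_det,
                    "pct_detectable": format_percent(n_det, n, decimals),
                }
            )
    return pd.DataFrame(rows, columns=["gene", "tier", "n", "n_detectable", "pct_detectable"])


@dataclass(frozen=True)
class SampleCoverageSummary:
    """Coverage rollup for one unique study‖sample."""

    sample_key: str
    any_detectable: bool
    n_panel_matches: int
    n_nonpanel: int
    has_extra_mutation: bool
    has_extra_high_tier_undetected: bool

    def __post_init__(self) -> None:
        if self.any_detectable != (self.n_panel_matches >= 1):
            raise ValueError("any_detectable inconsistent with match count")
        if self.has_extra_mutation and (self.n_panel_matches + self.n_nonpanel) < 2:
            raise ValueError("has_extra_mutation requires >= 2 records")


def sample_level_summary(
    results: list[MatchResult],
    high_tiers: tuple[str, ...] = HIGH_TIERS_DEFAULT,
) -> tuple[dict[str, SampleCoverageSummary], pd.DataFrame]:
    """Deduplicated sample-level rollup plus per-gene positive/negative totals.

    Each unique sample key appears exactly once; a specimen with several
    panel-detectable mutations counts once toward the positives. The per-gene
    table counts a sample under gene G if it carries >= 1 record of G, and as
    positive for G if any such record is panel-detectable.
    """
    by_sample: dict[str, list[MatchResult]] = {}
    for r in results:
        by_sample.setdefault(r.record.sample_key, []).append(r)

    samples: dict[str, SampleCoverageSummary] = {}
    for key, rs in by_sample.items():
        n_match = sum(1 for r in rs if r.matched)
        n_non = len(rs) - n_match
        has_extra = len(rs) >= 2
        high_undetected = any(
            (not r.matched) and r.record.tier in high_tiers for r in rs
        )
        samples[key] = SampleCoverageSummary(
            sample_key=key,
            any_detectable=n_match >= 1,
            n_panel_matches=n_match,
            n_nonpanel=n_non,
            has_extra_mutation=has_extra,
            has_extra_high_tier_undetected=has_extra and high_undetected,
        )

    genes = sorted({r.record.gene for r in results})
    rows = []
    for gene in genes:
        gene_samples = {
            key for key, rs in by_sample.items() if any(r.record.gene == gene for r in rs)
        }
        positives = {
            key
            for key in gene_samples
            if any(r.matched for r in by_sample[key] if r.record.gene == gene)
        }
        n, n_pos = len(gene_samples), len(positives)
        rows.append(
            {
                "gene": gene,
                "n_samples": n,
                "n_positive": n_pos,
                "n_negative": n - n_pos,
                "pct_positive": format_percent(n_pos, n, 0),
                "pct_negative": format_percent(n - n_pos, n, 0),
            }
        )
    per_gene = pd.DataFrame(
        rows,
        columns=["gene", "n_samples", "n_positive", "n_negative", "pct_positive", "pct_negative"],
    )
    return samples, per_gene


def disease_concordance(
    results: list[MatchResult],
    pairs: list[tuple[str, str]],
    high_tiers: tuple[str, ...] = HIGH_TIERS_DEFAULT,
) -> pd.DataFrame:
    """Case-level concordance per (index gene, diagnosis) pair.

    A case is a unique sample carrying >= 1 record of the index gene whose
    diagnosis matches; it is panel-positive if any of its index-gene records
    matches. The extra-mutation columns look across ALL the sample's records
    regardless of gene: ``n_extra`` counts cases with any record beyond the
    index mutation, and ``n_extra_high_tier`` counts cases that both carry an
    extra record and have >= 1 high-tier record the panel would not detect.
    Pairs with zero cases yield a row with blank percentages.
    """
    by_sample: dict[str, list[MatchResult]] = {}
    for r in results:
        by_sample.setdefault(r.record.sample_key, []).append(r)

    rows = []
    for gene, diagnosis in pairs:
        gene = gene.upper()
        case_keys = [
            key
            for key, rs in by_sample.items()
            if any(
                r.record.gene == gene and (r.record.diagnosis or "unspecified") == diagnosis
                for r in rs
            )
        ]
        n_cases = len(case_keys)
        n_pos = n_extra = n_extra_high = 0
        for key in case_keys:
            rs = by_sample[key]
            if any(r.matched for r in rs if r.record.gene == gene):
                n_pos += 1
            has_extra = len(rs) >= 2
            if has_extra:
                n_extra += 1
                if any((not r.matched) and r.record.tier in high_tiers for r in rs):
                    n_extra_high += 1
        def pct(n: int) -> str:
            return format_percent(n, n_cases, 0) if n_cases else ""
        rows.append(
            {
                "gene": gene,
                "diagnosis": diagnosis,
                "n_cases": n_cases,
                "n_idylla_positive": n_pos,
                "pct_positive": pct(n_pos),
                "n_idylla_negative": n_cases - n_pos,
                "pct_negative": pct(n_cases - n_pos),
                "n_extra": n_extra,
                "pct_extra": pct(n_extra),
                "n_extra_high_tier": n_extra_high,
                "pct_extra_high_tier": pct(n_extra_high),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene", "diagnosis", "n_cases",
            "n_idylla_positive", "pct_positive",
            "n_idylla_negative", "pct_negative",
            "n_extra", "pct_extra",
            "n_extra_high_tier", "pct_extra_high_tier",
        ],
    )
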