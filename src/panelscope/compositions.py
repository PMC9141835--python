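"""Reference cohort compositions from a published four-gene concordance study.

A published evaluation of a BRAF/EGFR/KRAS/NRAS hotspot-qPCR panel against
clinical NGS reported its results only as summary tables — per-gene variant
counts with tier breakdowns, unique-sample positivity over a large portal
aggregate, and per-disease case-level concordance with extra-mutation columns.
The underlying per-patient data are not shareable, but the printed
compositions themselves are exact inputs: this module encodes them as
generator strata so the full parse → match → dedup → summarize pipeline can
reconstruct every summary end-to-end, which is how the package's
reconstruction checks (tests and scripts/acceptance.py) exercise it.

Three compositions:

* :func:`variant_level_strata` — one stratum per gene with an exact joint
  tier x detectable plan (one record per sample): 159 BRAF / 133 NRAS /
  303 KRAS / 96 EGFR mutation-bearing samples with 123 / 118 / 283 / 76
  panel-detectable, Tier 1 subsets 147(123) / 127(116) / 294(276) / 73(71).
* :func:`sample_level_strata` — the portal-aggregate unique-sample counts:
  2483 BRAF (1346 detectable), 2960 EGFR (1122), 4667 KRAS (4232),
  1636 NRAS (1423), with duplicate export rows mixed in to exercise dedup.
* :func:`disease_strata` — the eight (gene, diagnosis) case strata with
  exact positive / extra / extra-plus-high-tier-undetected counts.
"""

from __future__ import annotations

from panelscope.synthetic_cohort import StratumSpec

__all__ = [
    "variant_level_strata",
    "sample_level_strata",
    "disease_strata",
    "DISEASE_PAIRS",
]


def variant_level_strata() -> list[StratumSpec]:
    """Per-gene variant-level compositions with exact tier plans.

    Each stratum emits one record per sample. The non-Tier-1 remainder is
    pooled as Tier 3; the reported summaries stratify Tier 1 only, so the
    label of the remainder does not affect any reconstructed number.
    """
    return [
        StratumSpec(
            "BRAF", "other", 159, n_detectable=123,
            tier_plan=(("1", 147, 123), ("3", 12, 0)),
        ),
        StratumSpec(
            "NRAS", "other", 133, n_detectable=118,
            tier_plan=(("1", 127, 116), ("3", 6, 2)),
        ),
        StratumSpec(
            "KRAS", "other", 303, n_detectable=283,
            tier_plan=(("1", 294, 276), ("3", 9, 7)),
        ),
        StratumSpec(
            "EGFR", "other", 96, n_detectable=76,
            tier_plan=(("1", 73, 71), ("3", 23, 5)),
        ),
    ]


def sample_level_strata(duplicate_rate: float = 0.03) -> list[StratumSpec]:
    """Portal-aggregate unique-sample compositions (one record per sample)."""
    counts = {
        "BRAF": (2483, 1346),
        "EGFR": (2960, 1122),
        "KRAS": (4667, 4232),
        "NRAS": (1636, 1423),
    }
    return [
        StratumSpec(
            gene, "other", n, n_detectable=det, duplicate_rate=duplicate_rate,
            study_id=f"aggregate-{gene}",
        )
        for gene, (n, det) in counts.items()
    ]


# (gene, diagnosis, n_cases, n_positive, n_extra, n_extra_high_tier_undetected)
_DISEASE_ROWS = [
    ("BRAF", "cutaneous melanoma", 27, 21, 8, 2),
    ("NRAS", "cutaneous melanoma", 28, 26, 12, 5),
    ("BRAF", "hairy cell leukemia", 11, 10, 3, 3),
    ("BRAF", "colorectal cancer", 53, 51, 17, 9),
    ("KRAS", "colorectal cancer", 65, 62, 24, 17),
    ("NRAS", "colorectal cancer", 3, 2, 2, 2),
    ("EGFR", "lung adenocarcinoma", 65, 56, 21, 7),
    ("KRAS", "lung adenocarcinoma", 158, 147, 25, 12),
]

DISEASE_PAIRS = [(gene, diagnosis) for gene, diagnosis, *_ in _DISEASE_ROWS]


def disease_strata() -> list[StratumSpec]:
    """The eight disease-specific case strata with exact extra-mutation counts."""
    return [
        StratumSpec(
            gene, diagnosis, n, n_detectable=pos, n_extra=extra, n_extra_high=high,
        )
        for gene, diagnosis, n, pos, extra, high in _DISEASE_ROWS
    ]


def expected_disease_counts() -> list[tuple[str, str, int, int, int, int]]:
    """The encoded (gene, diagnosis, n_cases, n_positive, n_extra, n_extra_high) rows."""
    return list(_DISEASE_ROWS)


# --------------------------------------------------------------------------
# End-to-end reconstruction: generate -> write TSV -> re-read (parse, dedup)
# -> gene filter / annotation join -> classify -> summarize.
# --------------------------------------------------------------------------

def _through_files(specs, panel, seed: int, workdir, *, gene_filter, stem: str):
    """Push one composition through the file-level pipeline; return MatchResults."""
    from pathlib import Path

    from panelscope import cohort_io, coverage
    from panelscope.synthetic_cohort import annotations_frame, generate_raw_rows

    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    rows, _labels = generate_raw_rows(specs, panel, seed)
    cohort_path = workdir / f"{stem}.tsv"
    cohort_io.write_cohort(
        cohort_io.CohortTable(tuple(rows), (("generate", len(rows), len(rows)),)),
        cohort_path,
    )
    table = cohort_io.read_cbioportal_export(cohort_path)
    if gene_filter is not None:
        table = cohort_io.filter_genes(table, gene_filter)
    table = cohort_io.attach_annotations(table, annotations_frame(rows))
    return coverage.classify(table, panel)


def run_reconstruction(seed: int, workdir, panel=None) -> dict:
    """Reconstruct all three summary surfaces through the full pipeline.

    Returns a dict with keys ``variant`` (gene -> GeneCoverageSummary),
    ``tier`` (DataFrame), ``sample`` (per-gene DataFrame) and ``disease``
    (concordance DataFrame). ``workdir`` receives the intermediate TSVs.
    """
    from pathlib import Path

    from panelscope import coverage
    from panelscope.panel_registry import default_panel_path, load_panel

    if panel is None:
        panel = load_panel(default_panel_path())
    workdir = Path(workdir)

    variant_results = _through_files(
        variant_level_strata(), panel, seed, workdir,
        gene_filter=sorted(panel.genes), stem="variant_level",
    )
    sample_results = _through_files(
        sample_level_strata(), panel, seed, workdir,
        gene_filter=sorted(panel.genes), stem="sample_level",
    )
    # no gene filter here: the extra-mutation columns need the co-occurring
    # off-panel gene records
    disease_results = _through_files(
        disease_strata(), panel, seed, workdir, gene_filter=None, stem="disease",
    )

    _, per_gene = coverage.sample_level_summary(sample_results)
    return {
        "variant": coverage.variant_level_summary(variant_results, decimals=1),
        "tier": coverage.tier_stratified_summary(variant_results),
        "sample": per_gene,
        "disease": coverage.disease_concordance(disease_results, DISEASE_PAIRS),
    }
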