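"""Record classification and the summary surfaces."""

import pytest

from panelscope.cohort_io import CohortRecord, CohortTable
from panelscope.coverage import (
    UndefinedPercentError,
    classify,
    disease_concordance,
    format_percent,
    sample_level_summary,
    tier_stratified_summary,
    variant_level_summary,
)
from panelscope.hgvs_core import VariantDescriptor, parse_cdna, parse_protein
from panelscope.panel_registry import PanelDefinition


def _rec(sample, gene, short, tier="unknown", diagnosis=None, study="s"):
    return CohortRecord(
        study_id=study,
        sample_id=sample,
        gene=gene,
        descriptor=VariantDescriptor(gene, protein=parse_protein(short)),
        raw_names=("", "", short),
        tier=tier,
        diagnosis=diagnosis,
    )


def _table(*records):
    return CohortTable(tuple(records), (("build", len(records), len(records)),))


def test_classify_matches_and_reasons(panel):
    table = _table(
        _rec("A", "BRAF", "p.V600E"),
        _rec("B", "KRAS", "p.G12F"),  # plausible but not on any cartridge
        _rec("C", "TP53", "p.R175H"),
    )
    results = classify(table, panel)
    assert [r.matched for r in results] == [True, False, False]
    assert results[0].match_level == "protein"
    assert results[1].reason == "key not in panel"
    assert results[2].reason == "gene not on panel"
    assert len(classify(_table(), panel)) == 0


def test_classify_cdna_level_and_no_shared_representation(panel):
    # V600E2 ships as a cDNA-only panel entry
    hit = CohortRecord(
        "s", "A", "BRAF",
        VariantDescriptor("BRAF", cdna=parse_cdna("c.1799_1800delinsAA")),
        raw_names=("c.1799_1800delinsAA", "", ""),
    )
    results = classify(_table(hit), panel)
    assert results[0].matched and results[0].match_level == "cdna"

    protein_only_panel = PanelDefinition(
        "p", "0", tuple(v for v in panel.variants_for("KRAS") if v.descriptor.cdna is None)
    )
    cdna_rec = CohortRecord(
        "s", "B", "KRAS", VariantDescriptor("KRAS", cdna=parse_cdna("c.999G>A")),
        raw_names=("c.999G>A", "", ""),
    )
    (res,) = classify(_table(cdna_rec), protein_only_panel)
    assert not res.matched and res.reason == "no shared representation"


def test_unparsable_record_reported_not_dropped(panel):
    rec = CohortRecord("s", "A", "BRAF", None, raw_names=("", "", "junk"), non_canonical=True)
    (res,) = classify(_table(rec), panel)
    assert not res.matched and res.reason == "unparsable variant name"


@pytest.mark.parametrize(
    "num,den,decimals,expected",
    [(123, 159, 1, "77.4%"), (4232, 4667, 0, "91%"), (0, 5, 0, "0%"), (1, 8, 0, "13%")],
)
def test_format_percent(num, den, decimals, expected):
    assert format_percent(num, den, decimals) == expected


def test_format_percent_half_up_not_bankers():
    # 2.5% and 3.5% both round away from zero at integer precision
    assert format_percent(25, 1000, 0) == "3%"
    assert format_percent(35, 1000, 0) == "4%"
    assert format_percent(125, 1000, 1) == "12.5%"


def test_format_percent_guards():
    with pytest.raises(UndefinedPercentError):
        format_percent(1, 0, 0)
    with pytest.raises(ValueError):
        format_percent(1, 2, 2)


def test_variant_level_summary_counts_and_omissions(panel):
    table = _table(
        _rec("A", "BRAF", "p.V600E", tier="1", diagnosis="cutaneous melanoma"),
        _rec("B", "BRAF", "p.V600E", tier="1"),
        _rec("C", "BRAF", "p.D594G", tier="3"),
    )
    out = variant_level_summary(classify(table, panel))
    assert set(out) == {"BRAF"}  # no 0/0 rows for absent genes
    s = out["BRAF"]
    assert (s.n_records, s.n_detectable) == (3, 2)
    assert s.by_tier == {"1": (2, 2), "3": (1, 0)}
    assert s.by_diagnosis == {"cutaneous melanoma": 1, "unspecified": 2}


def test_tier_stratified_unknown_stratum_partitions(panel):
    table = _table(_rec("A", "KRAS", "p.G12C"), _rec("B", "KRAS", "p.G12F"))
    df = tier_stratified_summary(classify(table, panel))
    assert df.to_dict(orient="records") == [
        {"gene": "KRAS", "tier": "unknown", "n": 2, "n_detectable": 1, "pct_detectable": "50%"}
    ]


def test_sample_level_counts_multi_hit_sample_once(panel):
    table = _table(
        _rec("A", "KRAS", "p.G12C"),
        _rec("A", "KRAS", "p.G12D"),  # same specimen, second detectable hit
        _rec("B", "KRAS", "p.G12F"),
    )
    samples, per_gene = sample_level_summary(classify(table, panel))
    a = samples["s‖A"]
    assert a.any_detectable and a.n_panel_matches == 2
    assert a.has_extra_mutation
    row = per_gene.set_index("gene").loc["KRAS"]
    assert (row["n_samples"], row["n_positive"]) == (2, 1)
    assert row["pct_positive"] == "50%"


def test_sample_level_empty_input():
    samples, per_gene = sample_level_summary([])
    assert samples == {}
    assert per_gene.empty


def test_disease_concordance_cases_and_extras(panel):
    records = [
        _rec("A", "BRAF", "p.V600E", tier="1", diagnosis="cutaneous melanoma"),
        _rec("A", "MAP2K1", "p.K57N", tier="1", diagnosis="cutaneous melanoma"),
        _rec("B", "BRAF", "p.D594G", tier="3", diagnosis="cutaneous melanoma"),
        _rec("C", "BRAF", "p.V600E", tier="1", diagnosis="colorectal cancer"),
    ]
    df = disease_concordance(
        classify(_table(*records), panel), [("BRAF", "cutaneous melanoma"), ("BRAF", "AML")]
    )
    mel = df.iloc[0]
    assert (mel["n_cases"], mel["n_idylla_positive"], mel["n_idylla_negative"]) == (2, 1, 1)
    assert mel["pct_positive"] == "50%"
    # sample A: extra MAP2K1 Tier 1 record, unmatched -> extra-high-tier case
    assert (mel["n_extra"], mel["n_extra_high_tier"]) == (1, 1)
    empty = df.iloc[1]
    assert empty["n_cases"] == 0 and empty["pct_positive"] == ""


def test_disease_concordance_single_matched_case(panel):
    df = disease_concordance(
        classify(_table(_rec("A", "BRAF", "p.V600E", diagnosis="hairy cell leukemia")), panel),
        [("BRAF", "hairy cell leukemia")],
    )
    row = df.iloc[0]
    assert row["pct_positive"] == "100%" and row["n_extra"] == 0


def test_monotonicity_panel_growth_never_loses_matches(panel):
    table = _table(
        _rec("A", "KRAS", "p.G12C"),
        _rec("B", "KRAS", "p.G12F"),
        _rec("C", "BRAF", "p.D594G"),
    )
    base = classify(table, panel)
    from panelscope.panel_registry import PanelVariant

    grown = PanelDefinition(
        "grown", "0",
        panel.variants
        + (
            PanelVariant(
                "KRAS",
                VariantDescriptor("KRAS", protein=parse_protein("p.G12F")),
                "G12F", "snv", "KRAS",
            ),
        ),
    )
    more = classify(table, grown)
    assert sum(r.matched for r in more) >= sum(r.matched for r in base)
    for before, after in zip(base, more):
        assert after.matched or not before.matched


def test_permutation_invariance_of_summaries(panel):
    records = [
        _rec(f"S{i}", gene, short, tier=t, diagnosis=d)
        for i, (gene, short, t, d) in enumerate(
            [
                ("BRAF", "p.V600E", "1", "cutaneous melanoma"),
                ("KRAS", "p.G12C", "1", "colorectal cancer"),
                ("KRAS", "p.G12F", "3", "colorectal cancer"),
                ("EGFR", "p.L858R", "1", "lung adenocarcinoma"),
                ("NRAS", "p.Q61R", "1", "AML"),
            ]
        )
    ]
    fwd = classify(_table(*records), panel)
    rev = classify(_table(*records[::-1]), panel)
    assert variant_level_summary(fwd) == variant_level_summary(rev)
    _, pg_fwd = sample_level_summary(fwd)
    _, pg_rev = sample_level_summary(rev)
    assert pg_fwd.equals(pg_rev)
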