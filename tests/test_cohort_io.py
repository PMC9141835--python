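"""Cohort table readers, deduplication, gene filtering, annotation joins."""

import pandas as pd
import pytest

from panelscope.cohort_io import (
    AnnotationConflictError,
    CohortFormatError,
    CohortTable,
    attach_annotations,
    filter_genes,
    read_cbioportal_export,
    read_cohort,
    read_maf_subset,
    write_cohort,
)

CBIO_HEADER = (
    "study name\tspecimen ID\tgene target\tcodon mutation name"
    "\tlong protein mutation name\tshort protein mutation name\n"
)


def _cbio_file(tmp_path, rows, name="cohort.tsv"):
    path = tmp_path / name
    path.write_text(CBIO_HEADER + "".join(r + "\n" for r in rows))
    return path


def test_dedup_and_provenance(tmp_path):
    rows = [
        "s1\tA\tBRAF\tc.1799T>A\tp.Val600Glu\tp.V600E",
        "s1\tA\tBRAF\tc.1799T>A\tp.Val600Glu\tp.V600E",  # exact duplicate
        "s1\tB\tBRAF\t\t\tp.V600E",
        "s1\tC\tKRAS\tc.35G>A\t\t",
        "s2\tA\tNRAS\t\tp.Gln61Arg\t",
    ]
    table = read_cbioportal_export(_cbio_file(tmp_path, rows))
    assert len(table) == 4
    steps = dict((s[0], (s[1], s[2])) for s in table.provenance)
    assert steps["dedup"] == (5, 4)
    # conservation through the chain: counts never increase
    for _, rows_in, rows_out in table.provenance:
        assert rows_out <= rows_in


def test_short_name_only_row_yields_protein_only_descriptor(tmp_path):
    table = read_cbioportal_export(_cbio_file(tmp_path, ["s\tA\tEGFR\t\t\tp.A379V"]))
    (rec,) = table.records
    assert rec.descriptor.protein is not None
    assert rec.descriptor.cdna is None
    assert rec.descriptor.protein.short_form() == "p.A379V"


def test_empty_name_rows_dropped_and_unparsable_flagged(tmp_path):
    rows = ["s\tA\tBRAF\t\t\t", "s\tB\tBRAF\t\t\tp.V600E", "s\tC\tBRAF\t\t\tgibberish!!"]
    table = read_cbioportal_export(_cbio_file(tmp_path, rows))
    assert len(table) == 2  # empty-name row dropped
    flagged = [r for r in table.records if r.non_canonical]
    assert len(flagged) == 1 and flagged[0].sample_id == "C"
    assert flagged[0].descriptor is None


def test_missing_specimen_column_is_format_error(tmp_path):
    path = tmp_path / "bad.tsv"
    path.write_text("study name\tgene target\tshort protein mutation name\ns\tBRAF\tp.V600E\n")
    with pytest.raises(CohortFormatError, match="sample_id"):
        read_cbioportal_export(path)


def test_header_synonyms_accepted(tmp_path):
    path = tmp_path / "syn.tsv"
    path.write_text("Study\tSample ID\tHugo Symbol\tHGVSp Short\nS1\tT1\tKRAS\tp.G12C\n")
    table = read_cbioportal_export(path)
    assert table.records[0].gene == "KRAS"
    assert table.records[0].sample_id == "T1"


def test_maf_subset_reader(tmp_path):
    path = tmp_path / "toy.maf"
    path.write_text(
        "#version 2.4\n"
        "Hugo_Symbol\tTumor_Sample_Barcode\tHGVSp_Short\tHGVSc\n"
        "KRAS\tT-01\tp.G12C\tc.34G>T\n"
        "BRAF\tT-02\tp.V600E\t\n"
    )
    table = read_maf_subset(path)
    assert len(table) == 2
    assert table.records[0].study_id == "toy"  # file stem
    assert table.records[1].descriptor.cdna is None
    assert table.records[1].descriptor.protein.short_form() == "p.V600E"


def test_maf_without_hgvs_columns_errors(tmp_path):
    path = tmp_path / "no_names.maf"
    path.write_text("Hugo_Symbol\tTumor_Sample_Barcode\nKRAS\tT-01\n")
    with pytest.raises(CohortFormatError):
        read_maf_subset(path)


def test_filter_genes_case_folded(tmp_path):
    rows = [
        "s\tA\tKRAS\t\t\tp.G12C",
        "s\tB\tKRAS\t\t\tp.G12D",
        "s\tC\tKRAS\t\t\tp.G12V",
        "s\tD\tTP53\t\t\tp.R175H",
    ]
    table = read_cbioportal_export(_cbio_file(tmp_path, rows))
    assert len(filter_genes(table, {"KRAS"})) == 3
    assert len(filter_genes(table, {"kras"})) == 3
    assert len(filter_genes(table, set())) == 0


def test_attach_annotations_sets_tier_and_diagnosis(tmp_path, caplog):
    rows = ["s\tA\tBRAF\t\t\tp.V600E", "s\tB\tKRAS\t\t\tp.G12C"]
    table = read_cbioportal_export(_cbio_file(tmp_path, rows))
    ann = pd.DataFrame(
        {
            "study_id": ["s", "s", "s"],
            "sample_id": ["A", "B", "MISSING"],
            "tier": ["1", "3", "1"],
            "diagnosis": ["cutaneous melanoma", "colorectal cancer", "other"],
        }
    )
    with caplog.at_level("WARNING"):
        out = attach_annotations(table, ann)
    assert [r.tier for r in out.records] == ["1", "3"]
    assert out.records[0].diagnosis == "cutaneous melanoma"
    assert "matched no record" in caplog.text


def test_attach_annotations_conflict_errors(tmp_path):
    table = read_cbioportal_export(_cbio_file(tmp_path, ["s\tA\tBRAF\t\t\tp.V600E"]))
    ann = pd.DataFrame(
        {"study_id": ["s", "s"], "sample_id": ["A", "A"], "tier": ["1", "2"]}
    )
    with pytest.raises(AnnotationConflictError):
        attach_annotations(table, ann)


def test_file_roundtrip_is_identity_on_records(tmp_path):
    rows = [
        "s1\tA\tBRAF\tc.1799T>A\tp.Val600Glu\tp.V600E",
        "s1\tB\tKRAS\tc.35G>A\t\t",
        "s2\tC\tEGFR\t\tp.Thr790Met\t",
    ]
    table = read_cbioportal_export(_cbio_file(tmp_path, rows))
    out = tmp_path / "canon.tsv"
    write_cohort(table, out)
    again = read_cohort(out)
    assert again.records == table.records
    write_cohort(again, tmp_path / "canon2.tsv")
    assert (tmp_path / "canon2.tsv").read_bytes() == out.read_bytes()


def test_dedup_and_filter_order_independent(tmp_path):
    rows = [
        "s\tA\tBRAF\t\t\tp.V600E",
        "s\tB\tKRAS\t\t\tp.G12C",
        "s\tB\tKRAS\t\t\tp.G12C",
        "s\tC\tTP53\t\t\tp.R175H",
    ]
    fwd = read_cbioportal_export(_cbio_file(tmp_path, rows, "fwd.tsv"))
    rev = read_cbioportal_export(_cbio_file(tmp_path, rows[::-1], "rev.tsv"))
    genes = {"BRAF", "KRAS"}
    multiset = lambda t: sorted(
        (r.study_id, r.sample_id, r.gene, r.raw_names) for r in filter_genes(t, genes).records
    )
    assert multiset(fwd) == multiset(rev)


def test_sample_key_separator_prevents_collisions():
    a = CohortTable(())  # noqa: F841  (construction sanity only)
    from panelscope.cohort_io import CohortRecord
    from panelscope.hgvs_core import VariantDescriptor, parse_protein

    d = VariantDescriptor("BRAF", protein=parse_protein("p.V600E"))
    r1 = CohortRecord("ab", "c", "BRAF", d)
    r2 = CohortRecord("a", "bc", "BRAF", d)
    assert r1.sample_key != r2.sample_key
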