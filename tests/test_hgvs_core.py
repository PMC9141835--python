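"""Variant-name parsing, canonical forms, and identity comparison."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from panelscope.hgvs_core import (
    AA_3TO1,
    AbsentRepresentationError,
    CdnaKind,
    MatchVerdict,
    ParseError,
    ProteinKind,
    VariantDescriptor,
    canonical_key,
    parse_cdna,
    parse_protein,
    same_variant,
    to_long_form,
    to_short_form,
)

RESIDUES = "ACDEFGHIKLMNPQRSTVWY"


@pytest.mark.parametrize(
    "text,kind,start,end,ref,alt",
    [
        ("c.901C>G", CdnaKind.substitution, 901, 901, "C", "G"),
        ("C.901c>g", CdnaKind.substitution, 901, 901, "C", "G"),
        ("901C>G", CdnaKind.substitution, 901, 901, "C", "G"),
        ("c.2235_2249del", CdnaKind.deletion, 2235, 2249, "", ""),
        ("c.1799_1800delinsAA", CdnaKind.delins, 1799, 1800, "", "AA"),
        ("c.2310_2311insGGT", CdnaKind.insertion, 2310, 2311, "", "GGT"),
        ("c.2300_2308dup", CdnaKind.duplication, 2300, 2308, "", ""),
        ("c.35del", CdnaKind.deletion, 35, 35, "", ""),
    ],
)
def test_parse_cdna_grammar(text, kind, start, end, ref, alt):
    change = parse_cdna(text)
    assert change.kind is kind
    assert (change.start, change.end) == (start, end)
    assert (change.ref_allele, change.alt_allele) == (ref, alt)


def test_cdna_case_normalization_equality():
    assert parse_cdna("C.901c>g") == parse_cdna("c.901C>G")


@pytest.mark.parametrize("bad", ["", "c.", "V600E", "c.abc", "c.12", "c.5A>5", "c.10_5del"])
def test_parse_cdna_rejects(bad):
    with pytest.raises(ParseError):
        parse_cdna(bad)


def test_cdna_roundtrip_preserves_retained_bases():
    change = parse_cdna("c.2235_2249delTTAAGAGAAGCAACA")
    assert parse_cdna(change.format()) == change
    # canonical key drops the redundant deleted sequence
    assert change.key_text() == "c.2235_2249del"
    assert parse_cdna("c.2235_2249del").key_text() == change.key_text()


@pytest.mark.parametrize(
    "text,kind,start,end,new",
    [
        ("p.Ala379Val", ProteinKind.missense, ("A", 379), ("A", 379), "V"),
        ("p.A379V", ProteinKind.missense, ("A", 379), ("A", 379), "V"),
        ("p.(Val600Glu)", ProteinKind.missense, ("V", 600), ("V", 600), "E"),
        ("Q61*", ProteinKind.nonsense, ("Q", 61), ("Q", 61), "*"),
        ("p.Gln61Ter", ProteinKind.nonsense, ("Q", 61), ("Q", 61), "*"),
        ("p.Glu746_Ala750del", ProteinKind.deletion, ("E", 746), ("A", 750), ""),
        ("p.E746_A750del", ProteinKind.deletion, ("E", 746), ("A", 750), ""),
        ("p.L747_P753delinsS", ProteinKind.delins, ("L", 747), ("P", 753), "S"),
        ("p.Leu747_Pro753delinsSer", ProteinKind.delins, ("L", 747), ("P", 753), "S"),
        ("p.A767_V769dup", ProteinKind.duplication, ("A", 767), ("V", 769), ""),
        ("p.D770_N771insSVD", ProteinKind.insertion, ("D", 770), ("N", 771), "SVD"),
        ("p.Asp770_Asn771insSerValAsp", ProteinKind.insertion, ("D", 770), ("N", 771), "SVD"),
        ("p.N771fs", ProteinKind.frameshift, ("N", 771), ("N", 771), ""),
        ("p.N771Tfs*12", ProteinKind.frameshift, ("N", 771), ("N", 771), ""),
        ("p.Asn771ThrfsTer12", ProteinKind.frameshift, ("N", 771), ("N", 771), ""),
    ],
)
def test_parse_protein_grammar(text, kind, start, end, new):
    change = parse_protein(text)
    assert change.kind is kind
    assert (change.start_residue, change.end_residue) == (start, end)
    assert change.new_residues == new


def test_long_and_short_spellings_parse_equal():
    assert parse_protein("p.Ala379Val") == parse_protein("p.A379V")
    assert parse_protein("p.Val600Glu") == parse_protein("V600E")


@pytest.mark.parametrize("bad", ["", "p.", "p.Abc379Val", "p.A379", "p.Ala379V", "p.379V", "c.901C>G"])
def test_parse_protein_rejects(bad):
    with pytest.raises(ParseError):
        parse_protein(bad)


@pytest.mark.parametrize(
    "text,short",
    [
        ("p.Ala379Val", "p.A379V"),
        ("p.A379V", "p.A379V"),
        ("p.Val600Glu", "p.V600E"),
        ("p.Glu746_Ala750del", "p.E746_A750del"),
        ("p.N771Tfs*12", "p.N771fs"),
        ("p.Gln61Ter", "p.Q61*"),
    ],
)
def test_to_short_form(text, short):
    assert to_short_form(parse_protein(text)) == short


def test_canonical_key_levels():
    d = VariantDescriptor("BRAF", protein=parse_protein("p.Val600Glu"))
    key = canonical_key(d, "protein")
    assert (key.gene, key.level, key.key_text) == ("BRAF", "protein", "p.V600E")
    with pytest.raises(AbsentRepresentationError):
        canonical_key(d, "cdna")
    with pytest.raises(ValueError):
        canonical_key(d, "genomic")


def test_same_variant_verdicts():
    braf_long = VariantDescriptor("BRAF", protein=parse_protein("p.Val600Glu"))
    braf_short = VariantDescriptor("BRAF", protein=parse_protein("p.V600E"))
    nras = VariantDescriptor("NRAS", protein=parse_protein("p.V600E"))
    kras_c = VariantDescriptor("KRAS", cdna=parse_cdna("c.35G>A"))
    kras_p = VariantDescriptor("KRAS", protein=parse_protein("p.G12D"))
    assert same_variant(braf_long, braf_short) is MatchVerdict.match_protein
    assert same_variant(braf_short, nras) is MatchVerdict.no_match
    assert same_variant(kras_c, kras_p) is MatchVerdict.indeterminate
    assert (
        same_variant(kras_c, VariantDescriptor("KRAS", cdna=parse_cdna("C.35g>a")))
        is MatchVerdict.match_cdna
    )


def test_protein_level_is_decisive_over_cdna():
    # both carry protein forms that differ: no match even though cDNA agrees
    a = VariantDescriptor("KRAS", cdna=parse_cdna("c.35G>A"), protein=parse_protein("p.G12D"))
    b = VariantDescriptor("KRAS", cdna=parse_cdna("c.35G>A"), protein=parse_protein("p.G12V"))
    assert same_variant(a, b) is MatchVerdict.no_match


def test_representation_invariance_1000_random_missense():
    """Long and short spellings of random missense events share one canonical key."""
    rng = np.random.default_rng(20260924)
    three = {one: code for code, one in AA_3TO1.items()}
    for _ in range(1000):
        ref, alt = rng.choice(list(RESIDUES), size=2, replace=False)
        pos = int(rng.integers(1, 3000))
        short = f"p.{ref}{pos}{alt}"
        long = f"p.{three[ref]}{pos}{three[alt]}"
        a = VariantDescriptor("GENE", protein=parse_protein(short))
        b = VariantDescriptor("GENE", protein=parse_protein(long))
        assert canonical_key(a, "protein") == canonical_key(b, "protein")
        assert same_variant(a, b) is MatchVerdict.match_protein


@st.composite
def protein_events(draw):
    kind = draw(st.sampled_from(["missense", "nonsense", "del", "dup", "ins", "delins", "fs"]))
    res = st.sampled_from(RESIDUES)
    a, b = draw(res), draw(res)
    s = draw(st.integers(1, 999))
    e = s + draw(st.integers(1, 20))
    if kind == "missense":
        alt = draw(res.filter(lambda x: x != a))
        return f"p.{a}{s}{alt}"
    if kind == "nonsense":
        return f"p.{a}{s}*"
    if kind == "fs":
        return f"p.{a}{s}fs"
    ins = "".join(draw(st.lists(res, min_size=1, max_size=4)))
    if kind == "ins":
        return f"p.{a}{s}_{b}{e}ins{ins}"
    if kind == "delins":
        return f"p.{a}{s}_{b}{e}delins{ins}"
    return f"p.{a}{s}_{b}{e}{'del' if kind == 'del' else 'dup'}"


@settings(derandomize=True, max_examples=300)
@given(protein_events())
def test_protein_roundtrip_and_long_short_agreement(text):
    """short -> long -> parse and short -> parse -> format fixed points."""
    change = parse_protein(text)
    assert parse_protein(to_short_form(change)) == change
    assert parse_protein(to_long_form(change)) == change
    assert to_short_form(parse_protein(to_long_form(change))) == to_short_form(change)


@settings(derandomize=True, max_examples=200)
@given(protein_events(), protein_events(), st.sampled_from(["BRAF", "KRAS"]))
def test_same_variant_symmetry(text_a, text_b, gene):
    a = VariantDescriptor(gene, protein=parse_protein(text_a))
    b = VariantDescriptor("BRAF", protein=parse_protein(text_b))
    assert same_variant(a, b) == same_variant(b, a)


def test_fixture_descriptors_roundtrip(panel):
    """Every descriptor shipped in the panel fixture survives parse -> format -> parse."""
    for v in panel.variants:
        if v.descriptor.cdna is not None:
            assert parse_cdna(v.descriptor.cdna.format()) == v.descriptor.cdna
        if v.descriptor.protein is not None:
            p = v.descriptor.protein
            assert parse_protein(to_short_form(p)) == p
            assert parse_protein(to_long_form(p)) == p


def test_oracle_equivalence_short_form_string_equality(panel):
    """Where both sides carry short protein forms, same_variant must agree with
    naive case-folded string equality of gene + short form."""
    descriptors = [
        v.descriptor for v in panel.variants if v.descriptor.protein is not None
    ]
    for a in descriptors[:20]:
        for b in descriptors[:20]:
            naive = (
                a.gene.upper() == b.gene.upper()
                and to_short_form(a.protein).upper() == to_short_form(b.protein).upper()
            )
            got = same_variant(a, b)
            assert (got is MatchVerdict.match_protein) == naive
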