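"""Parsing and canonical comparison of HGVS-style variant names.

Mutation exports spell the same event many ways: ``c.1799T>A`` at the coding-DNA
level, ``p.Val600Glu`` in three-letter protein form, ``p.V600E`` in one-letter
form, with or without the ``c.``/``p.`` prefixes or enclosing parentheses.
Hotspot-panel matching is string matching over these names, so everything here
exists to make two spellings of one event collide on a byte-identical canonical
key, and two different events never collide.

Scope is deliberately the subset of HGVS that appears in coding-region hotspot
lists and cohort exports: substitutions, deletions, insertions, duplications,
delins and frameshifts. Intronic, UTR, splice, genomic (``g.``) and allele
syntax are out of scope, as is any transcript- or reference-sequence-aware
normalisation (no 3'-shifting): comparison is over normalised text, which is
what assay package inserts and portal exports actually contain.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field

__all__ = [
    "ParseError",
    "AbsentRepresentationError",
    "CdnaKind",
    "ProteinKind",
    "MatchVerdict",
    "CdnaChange",
    "ProteinChange",
    "VariantDescriptor",
    "CanonicalKey",
    "parse_cdna",
    "format_cdna",
    "parse_protein",
    "to_short_form",
    "to_long_form",
    "canonical_key",
    "same_variant",
    "AA_3TO1",
    "AA_1TO3",
]


class ParseError(ValueError):
    """A variant name did not match the supported grammar."""


class AbsentRepresentationError(ValueError):
    """A descriptor lacks the representation level a caller asked for."""


class CdnaKind(str, enum.Enum):
    substitution = "substitution"
    deletion = "deletion"
    insertion = "insertion"
    duplication = "duplication"
    delins = "delins"


class ProteinKind(str, enum.Enum):
    missense = "missense"
    nonsense = "nonsense"
    deletion = "deletion"
    insertion = "insertion"
    duplication = "duplication"
    delins = "delins"
    frameshift = "frameshift"


class MatchVerdict(str, enum.Enum):
    match_protein = "match_protein"
    match_cdna = "match_cdna"
    no_match = "no_match"
    indeterminate = "indeterminate"


# 20 standard residues plus Ter (stop, '*') and Xaa (unknown, 'X').
AA_3TO1 = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
    "Ter": "*", "Xaa": "X",
}
AA_1TO3 = {one: three for three, one in AA_3TO1.items()}
_ONE_LETTER = set(AA_1TO3)

_AA3 = "|".join(AA_3TO1)  # alternation used inside the long-form grammar
_AA1 = r"[ACDEFGHIKLMNPQRSTVWYX*]"


@dataclass(frozen=True)
class CdnaChange:
    """One coding-DNA-level event, e.g. parsed from ``c.901C>G``.

    ``raw_text`` keeps the input spelling for audit trails but is excluded
    from equality: two spellings of the same event compare equal.
    """

    raw_text: str = field(compare=False)
    start: int
    end: int
    kind: CdnaKind
    ref_allele: str = ""
    alt_allele: str = ""

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ParseError(f"invalid cDNA position range {self.start}_{self.end}")
        if self.kind is CdnaKind.substitution and not (self.ref_allele and self.alt_allele):
            raise ParseError("substitution requires both ref and alt alleles")

    def format(self) -> str:
        """Lossless normalised rendering (re-parses to an equal value)."""
        return format_cdna(self)

    def key_text(self) -> str:
        """Canonical comparison text.

        Differs from :meth:`format` in dropping bases that are redundant given
        the position range (the deleted/duplicated sequence), so that
        ``c.2235_2249del`` and ``c.2235_2249delTTAAGAGAAGCAACA`` — two common
        spellings of one deletion — compare equal.
        """
        return _render_cdna(self, include_redundant=False)


@dataclass(frozen=True)
class ProteinChange:
    """One protein-level event, representation-independent.

    ``p.Ala379Val`` and ``p.A379V`` parse to equal values; residues are stored
    as (one-letter code, position) pairs. ``new_residues`` holds the inserted
    or substituted residues in one-letter code ('' where not applicable).
    Frameshifts are canonicalised to residue+position+``fs``: extension
    lengths (``fs*12``) are parsed but discarded, because hotspot target lists
    spell frameshifts without them and keeping them would only manufacture
    false mismatches.
    """

    raw_text: str = field(compare=False)
    start_residue: tuple[str, int]
    end_residue: tuple[str, int]
    kind: ProteinKind
    new_residues: str = ""

    def __post_init__(self) -> None:
        for aa, pos in (self.start_residue, self.end_residue):
            if aa not in _ONE_LETTER:
                raise ParseError(f"unknown residue code {aa!r}")
            if pos < 1:
                raise ParseError(f"invalid residue position {pos}")
        if self.end_residue[1] < self.start_residue[1]:
            raise ParseError("end residue precedes start residue")
        for aa in self.new_residues:
            if aa not in _ONE_LETTER:
                raise ParseError(f"unknown residue code {aa!r} in new residues")

    def short_form(self) -> str:
        return to_short_form(self)

    def long_form(self) -> str:
        return to_long_form(self)


@dataclass(frozen=True)
class VariantDescriptor:
    """One mutation in up to three representations: gene + cDNA and/or protein."""

    gene: str
    cdna: CdnaChange | None = None
    protein: ProteinChange | None = None

    def __post_init__(self) -> None:
        if not self.gene:
            raise ValueError("gene symbol must be non-empty")
        object.__setattr__(self, "gene", self.gene.strip().upper())
        if self.cdna is None and self.protein is None:
            raise ValueError("descriptor needs at least one of cdna/protein")

    @property
    def levels(self) -> frozenset[str]:
        out = set()
        if self.cdna is not None:
            out.add("cdna")
        if self.protein is not None:
            out.add("protein")
        return frozenset(out)


@dataclass(frozen=True)
class CanonicalKey:
    """Deterministic comparison key at one representation level."""

    gene: str
    level: str  # "cdna" | "protein"
    key_text: str


# --------------------------------------------------------------------------
# cDNA grammar
# --------------------------------------------------------------------------

_CDNA_PATTERNS: list[tuple[CdnaKind, re.Pattern[str]]] = [
    (CdnaKind.substitution, re.compile(r"^(\d+)([ACGT])>([ACGT])$", re.IGNORECASE)),
    (CdnaKind.delins, re.compile(r"^(\d+)(?:_(\d+))?delins([ACGT]+)$", re.IGNORECASE)),
    (CdnaKind.deletion, re.compile(r"^(\d+)(?:_(\d+))?del([ACGT]*)$", re.IGNORECASE)),
    (CdnaKind.insertion, re.compile(r"^(\d+)_(\d+)ins([ACGT]+)$", re.IGNORECASE)),
    (CdnaKind.duplication, re.compile(r"^(\d+)(?:_(\d+))?dup([ACGT]*)$", re.IGNORECASE)),
]


def parse_cdna(text: str) -> CdnaChange:
    """Parse a coding-DNA variant name such as ``c.901C>G``.

    The ``c.`` prefix is optional on input; nucleotide case is normalised to
    uppercase. Raises :class:`ParseError` on anything outside the supported
    grammar, naming the offending text.
    """
    raw = text
    body = text.strip()
    if not body:
        raise ParseError("empty cDNA name")
    if body[:2].lower() == "c.":
        body = body[2:]
    for kind, pattern in _CDNA_PATTERNS:
        m = pattern.match(body)
        if m is None:
            continue
        if kind is CdnaKind.substitution:
            pos = int(m.group(1))
            return CdnaChange(
                raw, pos, pos, kind,
                ref_allele=m.group(2).upper(), alt_allele=m.group(3).upper(),
            )
        start = int(m.group(1))
        end = int(m.group(2)) if m.group(2) else start
        tail = (m.group(3) or "").upper()
        if kind in (CdnaKind.deletion, CdnaKind.duplication):
            return CdnaChange(raw, start, end, kind, ref_allele=tail)
        return CdnaChange(raw, start, end, kind, alt_allele=tail)
    raise ParseError(f"unrecognised cDNA variant name: {text!r}")


def _render_cdna(change: CdnaChange, include_redundant: bool) -> str:
    span = (
        f"{change.start}"
        if change.start == change.end
        else f"{change.start}_{change.end}"
    )
    k = change.kind
    if k is CdnaKind.substitution:
        return f"c.{change.start}{change.ref_allele}>{change.alt_allele}"
    if k is CdnaKind.deletion:
        tail = change.ref_allele if include_redundant else ""
        return f"c.{span}del{tail}"
    if k is CdnaKind.duplication:
        tail = change.ref_allele if include_redundant else ""
        return f"c.{span}dup{tail}"
    if k is CdnaKind.insertion:
        return f"c.{span}ins{change.alt_allele}"
    return f"c.{span}delins{change.alt_allele}"


def format_cdna(change: CdnaChange) -> str:
    """Normalised text that re-parses to a value equal to ``change``."""
    return _render_cdna(change, include_redundant=True)


# --------------------------------------------------------------------------
# Protein grammar: each name must be entirely long (3-letter) or entirely
# short (1-letter) form; mixing the two is rejected as ambiguous.
# --------------------------------------------------------------------------

def _protein_patterns(aa: str, stop_ok: str) -> dict[str, re.Pattern[str]]:
    res = f"(?:{aa})"
    return {
        "substitution": re.compile(rf"^({res})(\d+)({stop_ok})$"),
        "delins": re.compile(rf"^({res})(\d+)(?:_({res})(\d+))?delins((?:{res})+)$"),
        "deletion": re.compile(rf"^({res})(\d+)(?:_({res})(\d+))?del$"),
        "insertion": re.compile(rf"^({res})(\d+)_({res})(\d+)ins((?:{res})+)$"),
        "duplication": re.compile(rf"^({res})(\d+)(?:_({res})(\d+))?dup$"),
        "frameshift": re.compile(
            rf"^({res})(\d+)(?:{res})?fs(?:\*?\d+|(?:Ter|X)\d*|\*\??)?$"
        ),
    }


_LONG = _protein_patterns(_AA3, rf"(?:{_AA3})|\*")
_SHORT = _protein_patterns(_AA1, _AA1)


def _aa1(token: str) -> str:
    if len(token) == 1:
        return token
    return AA_3TO1[token]


def _split_residues(tokens: str) -> str:
    """One-letter string from a run of residue tokens (either spelling)."""
    if re.fullmatch(rf"(?:{_AA3})+", tokens):
        return "".join(AA_3TO1[tokens[i : i + 3]] for i in range(0, len(tokens), 3))
    return tokens


def parse_protein(text: str) -> ProteinChange:
    """Parse a protein variant name in long or short spelling.

    Accepts with/without the ``p.`` prefix and with/without enclosing
    parentheses (the HGVS predicted-consequence convention ``p.(Val600Glu)``).
    The result is representation-independent: long and short spellings of one
    event parse to equal values.
    """
    raw = text
    body = text.strip()
    if not body:
        raise ParseError("empty protein name")
    if body[:2].lower() == "p.":
        body = body[2:]
    if body.startswith("(") and body.endswith(")"):
        body = body[1:-1]
    if not body:
        raise ParseError(f"empty protein name: {text!r}")

    for grammar in (_LONG, _SHORT):
        change = _try_protein_grammar(raw, body, grammar)
        if change is not None:
            return change
    raise ParseError(f"unrecognised protein variant name: {text!r}")


def _try_protein_grammar(
    raw: str, body: str, grammar: dict[str, re.Pattern[str]]
) -> ProteinChange | None:
    m = grammar["substitution"].match(body)
    if m:
        ref, pos, alt = _aa1(m.group(1)), int(m.group(2)), _aa1(m.group(3))
        kind = ProteinKind.nonsense if alt == "*" else ProteinKind.missense
        return ProteinChange(raw, (ref, pos), (ref, pos), kind, new_residues=alt)
    m = grammar["delins"].match(body)
    if m:
        start = (_aa1(m.group(1)), int(m.group(2)))
        end = (_aa1(m.group(3)), int(m.group(4))) if m.group(3) else start
        return ProteinChange(raw, start, end, ProteinKind.delins, _split_residues(m.group(5)))
    m = grammar["deletion"].match(body)
    if m:
        start = (_aa1(m.group(1)), int(m.group(2)))
        end = (_aa1(m.group(3)), int(m.group(4))) if m.group(3) else start
        return ProteinChange(raw, start, end, ProteinKind.deletion)
    m = grammar["insertion"].match(body)
    if m:
        start = (_aa1(m.group(1)), int(m.group(2)))
        end = (_aa1(m.group(3)), int(m.group(4)))
        return ProteinChange(raw, start, end, ProteinKind.insertion, _split_residues(m.group(5)))
    m = grammar["duplication"].match(body)
    if m:
        start = (_aa1(m.group(1)), int(m.group(2)))
        end = (_aa1(m.group(3)), int(m.group(4))) if m.group(3) else start
        return ProteinChange(raw, start, end, ProteinKind.duplication)
    m = grammar["frameshift"].match(body)
    if m:
        start = (_aa1(m.group(1)), int(m.group(2)))
        return ProteinChange(raw, start, start, ProteinKind.frameshift)
    return None


def to_short_form(change: ProteinChange) -> str:
    """Canonical one-letter rendering, ``p.`` prefix, no parentheses."""
    (a, s), (b, e) = change.start_residue, change.end_residue
    span = f"{a}{s}" if (s == e and change.kind is not ProteinKind.insertion) else f"{a}{s}_{b}{e}"
    k = change.kind
    if k in (ProteinKind.missense, ProteinKind.nonsense):
        return f"p.{a}{s}{change.new_residues}"
    if k is ProteinKind.deletion:
        return f"p.{span}del"
    if k is ProteinKind.duplication:
        return f"p.{span}dup"
    if k is ProteinKind.insertion:
        return f"p.{a}{s}_{b}{e}ins{change.new_residues}"
    if k is ProteinKind.delins:
        return f"p.{span}delins{change.new_residues}"
    return f"p.{a}{s}fs"


def to_long_form(change: ProteinChange) -> str:
    """Three-letter rendering of the same event (parses back equal)."""
    short = to_short_form(change)[2:]  # strip "p."

    def widen(m: re.Match[str]) -> str:
        return AA_1TO3[m.group(0)]

    # every isolated residue letter in the short form maps through the 1->3
    # table; runs of inserted residues are widened letter-by-letter too
    long = re.sub(rf"{_AA1}", widen, short)
    return f"p.{long}"


# --------------------------------------------------------------------------
# Canonical keys and variant identity
# --------------------------------------------------------------------------

def canonical_key(descriptor: VariantDescriptor, level: str) -> CanonicalKey:
    """Deterministic comparison key for ``descriptor`` at ``level``.

    Protein keys are the canonical short form; cDNA keys are the normalised
    event text with redundant deleted/duplicated bases dropped. Raises
    :class:`AbsentRepresentationError` if the descriptor does not carry the
    requested level.
    """
    if level == "protein":
        if descriptor.protein is None:
            raise AbsentRepresentationError(
                f"{descriptor.gene} descriptor has no protein representation"
            )
        return CanonicalKey(descriptor.gene, "protein", descriptor.protein.short_form())
    if level == "cdna":
        if descriptor.cdna is None:
            raise AbsentRepresentationError(
                f"{descriptor.gene} descriptor has no cDNA representation"
            )
        return CanonicalKey(descriptor.gene, "cdna", descriptor.cdna.key_text())
    raise ValueError(f"unknown representation level {level!r}")


def same_variant(a: VariantDescriptor, b: VariantDescriptor) -> MatchVerdict:
    """Decide whether two descriptors name the same event.

    Genes must match for any positive verdict. The protein level is compared
    first (long and short spellings collapse to one canonical key); when both
    descriptors carry protein forms that comparison is decisive. Otherwise the
    cDNA level is compared. ``indeterminate`` is returned only when the two
    descriptors share no representation level at all.
    """
    if a.gene != b.gene:
        return MatchVerdict.no_match
    if a.protein is not None and b.protein is not None:
        if a.protein.short_form() == b.protein.short_form():
            return MatchVerdict.match_protein
        return MatchVerdict.no_match
    if a.cdna is not None and b.cdna is not None:
        if a.cdna.key_text() == b.cdna.key_text():
            return MatchVerdict.match_cdna
        return MatchVerdict.no_match
    return MatchVerdict.indeterminate
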