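"""Reading, filtering and annotating cohort mutation tables.

Two input dialects are supported:

* the cBioPortal-style export — a tab-delimited table with a study name,
  specimen ID, gene symbol, and up to three variant-name columns (coding-DNA
  name, long protein name, short protein name);
* a MAF subset — the standard somatic Mutation Annotation Format columns
  ``Hugo_Symbol``, ``Tumor_Sample_Barcode`` and any of ``HGVSc`` / ``HGVSp`` /
  ``HGVSp_Short``, with ``#`` comment lines.

Both are mapped onto one record shape and pushed through the same filter
chain: drop rows with no variant name at all, drop exact-duplicate rows,
restrict to the genes of interest. Every step logs before/after row counts
into the table's provenance so conservation (rows_in == rows_out + dropped)
is checkable after the fact.

A record whose variant names fail the supported grammar is not discarded: it
keeps its raw text and is flagged non-canonical, so it flows through the
pipeline and lands in the "not detectable" bucket with an auditable reason
rather than silently vanishing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

from panelscope.hgvs_core import ParseError, VariantDescriptor, parse_cdna, parse_protein

__all__ = [
    "SAMPLE_KEY_SEP",
    "TIERS",
    "CohortFormatError",
    "AnnotationConflictError",
    "CohortRecord",
    "CohortTable",
    "read_cbioportal_export",
    "read_maf_subset",
    "filter_genes",
    "attach_annotations",
    "write_cohort",
    "read_cohort",
]

logger = logging.getLogger(__name__)

# Explicit separator so ("ab","c") and ("a","bc") cannot collide.
SAMPLE_KEY_SEP = "‖"  # '‖'

TIERS = ("1", "2", "3", "4", "unknown")

# header synonyms, lowercased/despaced; extensible by callers
_CBIO_SYNONYMS: dict[str, tuple[str, ...]] = {
    "study_id": ("studyname", "study", "studyid", "cancerstudy"),
    "sample_id": ("specimenid", "sampleid", "sample", "specimen", "tumorsamplebarcode"),
    "gene": ("genetarget", "gene", "genesymbol", "hugosymbol"),
    "cdna": ("codonmutationname", "cdnachange", "hgvsc", "codonmutation"),
    "protein_long": ("longproteinmutationname", "proteinchangelong", "hgvsp"),
    "protein_short": ("shortproteinmutationname", "proteinchange", "hgvspshort"),
}


class CohortFormatError(ValueError):
    """An input table is missing mandatory columns or is otherwise unreadable."""


class AnnotationConflictError(ValueError):
    """One annotation key maps to two different values."""


@dataclass(frozen=True)
class CohortRecord:
    """One observed mutation in one sample.

    ``descriptor`` is None only for rows whose variant names all failed the
    grammar; such records keep ``raw_names`` and are flagged
    ``non_canonical`` so matching can still report them with a reason.
    """

    study_id: str
    sample_id: str
    gene: str
    descriptor: VariantDescriptor | None
    raw_names: tuple[str, str, str] = ("", "", "")  # (cdna, long, short) as read
    tier: str = "unknown"
    diagnosis: str | None = None
    non_canonical: bool = False

    def __post_init__(self) -> None:
        if not self.study_id or not self.sample_id:
            raise ValueError("study_id and sample_id must be non-empty")
        object.__setattr__(self, "gene", self.gene.strip().upper())
        if self.tier not in TIERS:
            raise ValueError(f"tier must be one of {TIERS}, got {self.tier!r}")

    @property
    def sample_key(self) -> str:
        return f"{self.study_id}{SAMPLE_KEY_SEP}{self.sample_id}"


@dataclass(frozen=True)
class CohortTable:
    """An ordered record collection plus its filter-chain provenance.

    ``provenance`` is a tuple of (step name, rows_in, rows_out); every filter
    appends one entry, so rows dropped at each step are reconstructable.
    """

    records: tuple[CohortRecord, ...]
    provenance: tuple[tuple[str, int, int], ...] = ()

    def __len__(self) -> int:
        return len(self.records)

    def with_step(self, step: str, rows_in: int, records) -> "CohortTable":
        records = tuple(records)
        return CohortTable(records, self.provenance + ((step, rows_in, len(records)),))


def _norm_header(h: str) -> str:
    return "".join(ch for ch in h.lower() if ch.isalnum())


def _resolve_columns(header: list[str], synonyms: dict[str, tuple[str, ...]]) -> dict[str, str]:
    normed = {_norm_header(h): h for h in header}
    out = {}
    for canon, alts in synonyms.items():
        for alt in alts:
            if alt in normed:
                out[canon] = normed[alt]
                break
    return out


def _parse_names(cdna_text: str, long_text: str, short_text: str,
                 gene: str) -> tuple[VariantDescriptor | None, bool]:
    """Build a descriptor from up to three name columns.

    Returns (descriptor, non_canonical). The long and short protein columns
    describe the same event; the short form is preferred when both parse, and
    a disagreement between them is treated as non-canonical rather than
    guessed at.
    """
    cdna = None
    bad = False
    if cdna_text:
        try:
            cdna = parse_cdna(cdna_text)
        except ParseError:
            bad = True
    protein = None
    parsed = []
    for text in (short_text, long_text):
        if not text:
            continue
        try:
            parsed.append(parse_protein(text))
        except ParseError:
            bad = True
    if len(parsed) == 2 and parsed[0] != parsed[1]:
        bad = True
        parsed = []
    if parsed:
        protein = parsed[0]
    if cdna is None and protein is None:
        return None, True
    return VariantDescriptor(gene=gene, cdna=cdna, protein=protein), bad


def _dedup(records: list[CohortRecord]) -> list[CohortRecord]:
    seen: set[tuple] = set()
    out = []
    for r in records:
        key = (r.study_id, r.sample_id, r.gene, r.raw_names)
        if key in seen:
            continue
        seen.add(key)
        out.append(r)
    return out


def read_cbioportal_export(path: str | Path, *, study_default: str | None = None,
                           synonyms: dict[str, tuple[str, ...]] | None = None) -> CohortTable:
    """Read a cBioPortal-style tab-delimited mutation export.

    Mandatory columns (under any recognised synonym): study name, specimen
    ID, gene. At least one of the three variant-name columns must exist.
    Rows with all three name cells empty are dropped (logged); exact
    duplicate rows (all six retained columns equal after whitespace trim)
    are dropped.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, comment=None, keep_default_na=False)
    cols = _resolve_columns(list(df.columns), {**_CBIO_SYNONYMS, **(synonyms or {})})
    missing = [c for c in ("sample_id", "gene") if c not in cols]
    if "study_id" not in cols and study_default is None:
        missing.insert(0, "study_id")
    if missing:
        raise CohortFormatError(
            f"{path.name}: missing mandatory column(s) {missing}; found headers {list(df.columns)}"
        )
    if not any(c in cols for c in ("cdna", "protein_long", "protein_short")):
        raise CohortFormatError(f"{path.name}: no variant-name column found")

    def cell(row, canon: str) -> str:
        col = cols.get(canon)
        return str(row[col]).strip() if col else ""

    n_total = len(df)
    records: list[CohortRecord] = []
    n_empty = 0
    for _, row in df.iterrows():
        names = (cell(row, "cdna"), cell(row, "protein_long"), cell(row, "protein_short"))
        if not any(names):
            n_empty += 1
            continue
        gene = cell(row, "gene").upper()
        descriptor, bad = _parse_names(*names, gene=gene)
        records.append(
            CohortRecord(
                study_id=cell(row, "study_id") or study_default or path.stem,
                sample_id=cell(row, "sample_id"),
                gene=gene,
                descriptor=descriptor,
                raw_names=names,
                non_canonical=bad,
            )
        )
    if n_empty:
        logger.info("%s: dropped %d rows with no variant name", path.name, n_empty)
    table = CohortTable((), ()).with_step(f"read:{path.name}", n_total, records)
    deduped = _dedup(records)
    return table.with_step("dedup", len(records), deduped)


_MAF_NAME_COLS = ("HGVSc", "HGVSp", "HGVSp_Short")


def read_maf_subset(path: str | Path) -> CohortTable:
    """Read the MAF columns this analysis needs.

    Requires ``Hugo_Symbol``, ``Tumor_Sample_Barcode`` and at least one of
    ``HGVSc``/``HGVSp``/``HGVSp_Short``. ``#`` comment lines are skipped.
    The study identifier defaults to the file stem (MAF carries none).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#", keep_default_na=False)
    for col in ("Hugo_Symbol", "Tumor_Sample_Barcode"):
        if col not in df.columns:
            raise CohortFormatError(f"{path.name}: missing MAF column {col}")
    if not any(c in df.columns for c in _MAF_NAME_COLS):
        raise CohortFormatError(
            f"{path.name}: none of {_MAF_NAME_COLS} present"
        )

    n_total = len(df)
    records: list[CohortRecord] = []
    n_empty = 0
    for _, row in df.iterrows():
        cdna = str(row.get("HGVSc", "")).strip()
        long_p = str(row.get("HGVSp", "")).strip()
        short_p = str(row.get("HGVSp_Short", "")).strip()
        if not (cdna or long_p or short_p):
            n_empty += 1
            continue
        gene = str(row["Hugo_Symbol"]).strip().upper()
        descriptor, bad = _parse_names(cdna, long_p, short_p, gene=gene)
        records.append(
            CohortRecord(
                study_id=path.stem,
                sample_id=str(row["Tumor_Sample_Barcode"]).strip(),
                gene=gene,
                descriptor=descriptor,
                raw_names=(cdna, long_p, short_p),
                non_canonical=bad,
            )
        )
    if n_empty:
        logger.info("%s: dropped %d rows with no variant name", path.name, n_empty)
    table = CohortTable((), ()).with_step(f"read:{path.name}", n_total, records)
    deduped = _dedup(records)
    return table.with_step("dedup", len(records), deduped)


def filter_genes(table: CohortTable, genes) -> CohortTable:
    """Keep only records of the given genes (symbols case-folded)."""
    wanted = {g.strip().upper() for g in genes}
    kept = [r for r in table.records if r.gene in wanted]
    return table.with_step(f"filter_genes:{','.join(sorted(wanted))}", len(table.records), kept)


def attach_annotations(table: CohortTable, annotations: pd.DataFrame) -> CohortTable:
    """Join tier and/or diagnosis annotations onto the table.

    ``annotations`` carries ``study_id`` + ``sample_id`` key columns and any
    of ``tier`` (per-record when a ``gene`` column is also present, otherwise
    per-sample) and ``diagnosis``. Unannotated records keep tier "unknown"
    and no diagnosis. Conflicting values for one key raise
    :class:`AnnotationConflictError`; keys matching no record are warned
    about and ignored.
    """
    ann = annotations.copy()
    for col in ("study_id", "sample_id"):
        if col not in ann.columns:
            raise CohortFormatError(f"annotation table missing key column {col}")
    has_gene = "gene" in ann.columns
    ann["study_id"] = ann["study_id"].astype(str).str.strip()
    ann["sample_id"] = ann["sample_id"].astype(str).str.strip()
    if has_gene:
        ann["gene"] = ann["gene"].astype(str).str.strip().str.upper()

    def build_map(value_col: str) -> dict[tuple, str]:
        if value_col not in ann.columns:
            return {}
        out: dict[tuple, str] = {}
        for _, row in ann.iterrows():
            val = str(row[value_col]).strip()
            if not val or val.lower() == "nan":
                continue
            key: tuple = (row["study_id"], row["sample_id"])
            if has_gene and value_col == "tier":
                key = key + (row["gene"],)
            if key in out and out[key] != val:
                raise AnnotationConflictError(
                    f"conflicting {value_col} values {out[key]!r} vs {val!r} for key {key}"
                )
            out[key] = val
        return out

    tier_map = build_map("tier")
    diag_map = build_map("diagnosis")

    record_keys = {(r.study_id, r.sample_id) for r in table.records}
    record_keys |= {(r.study_id, r.sample_id, r.gene) for r in table.records}
    unmatched = (set(tier_map) | set(diag_map)) - record_keys
    if unmatched:
        logger.warning("%d annotation key(s) matched no record", len(unmatched))

    out_records = []
    for r in table.records:
        tier = tier_map.get((r.study_id, r.sample_id, r.gene)) or tier_map.get(
            (r.study_id, r.sample_id)
        )
        diagnosis = diag_map.get((r.study_id, r.sample_id))
        out_records.append(
            replace(
                r,
                tier=str(tier) if tier is not None else r.tier,
                diagnosis=diagnosis if diagnosis is not None else r.diagnosis,
            )
        )
    return table.with_step("attach_annotations", len(table.records), out_records)


_CANON_COLUMNS = [
    "study name", "specimen ID", "gene target", "codon mutation name",
    "long protein mutation name", "short protein mutation name", "tier", "diagnosis",
]


def write_cohort(table: CohortTable, path: str | Path) -> None:
    """Write the canonical cohort TSV (UTF-8, Unix newlines, fixed column order)."""
    rows = []
    for r in table.records:
        rows.append(
            {
                "study name": r.study_id,
                "specimen ID": r.sample_id,
                "gene target": r.gene,
                "codon mutation name": r.raw_names[0],
                "long protein mutation name": r.raw_names[1],
                "short protein mutation name": r.raw_names[2],
                "tier": r.tier,
                "diagnosis": r.diagnosis or "",
            }
        )
    df = pd.DataFrame(rows, columns=_CANON_COLUMNS)
    df.to_csv(path, sep="\t", index=False, lineterminator="\n", encoding="utf-8")


def read_cohort(path: str | Path) -> CohortTable:
    """Read a table written by :func:`write_cohort` (round-trips records)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    records = []
    for _, row in df.iterrows():
        names = (
            str(row["codon mutation name"]).strip(),
            str(row["long protein mutation name"]).strip(),
            str(row["short protein mutation name"]).strip(),
        )
        if not any(names):
            continue
        gene = str(row["gene target"]).strip().upper()
        descriptor, bad = _parse_names(*names, gene=gene)
        records.append(
            CohortRecord(
                study_id=str(row["study name"]).strip(),
                sample_id=str(row["specimen ID"]).strip(),
                gene=gene,
                descriptor=descriptor,
                raw_names=names,
                tier=str(row.get("tier", "unknown")).strip() or "unknown",
                diagnosis=(str(row.get("diagnosis", "")).strip() or None),
                non_canonical=bad,
            )
        )
    return CohortTable((), ()).with_step(f"read:{path.name}", len(df), records)
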