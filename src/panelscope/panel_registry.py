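"""The assay's detectable-variant list (panel definition), loaded from file.

A hotspot qPCR cartridge detects a finite, vendor-published list of variants.
This module represents that list as an ordered collection of single concrete
variants (grouped vendor labels such as "V600E/E2/D" are expanded at
file-authoring time), validates it, and answers membership queries through the
same canonical-key machinery used for cohort records.

File formats: TSV with columns ``gene``, ``cdna``, ``protein``,
``vendor_label``, ``class``, ``cartridge`` (empty cells where a representation
is absent), or a JSON array of objects with identical field names. See
docs/panel_format.md.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from importlib import resources

from panelscope.hgvs_core import (
    MatchVerdict,
    ParseError,
    VariantDescriptor,
    canonical_key,
    parse_cdna,
    parse_protein,
    same_variant,
)

__all__ = [
    "PanelVariant",
    "PanelDefinition",
    "PanelLoadError",
    "load_panel",
    "panel_summary",
    "default_panel_path",
]

_COLUMNS = ("gene", "cdna", "protein", "vendor_label", "class", "cartridge")


class PanelLoadError(ValueError):
    """A panel file failed schema or uniqueness validation."""


@dataclass(frozen=True)
class PanelVariant:
    """One concrete assay-detectable variant."""

    gene: str
    descriptor: VariantDescriptor
    vendor_label: str
    variant_class: str  # "snv" | "indel"
    cartridge: str

    def __post_init__(self) -> None:
        if self.gene != self.descriptor.gene:
            raise PanelLoadError(
                f"panel row gene {self.gene!r} != descriptor gene {self.descriptor.gene!r}"
            )
        if self.variant_class not in ("snv", "indel"):
            raise PanelLoadError(f"unknown variant class {self.variant_class!r}")


@dataclass(frozen=True)
class PanelDefinition:
    """An ordered, validated detectable-variant list for one assay."""

    name: str
    version: str
    variants: tuple[PanelVariant, ...]
    genes: frozenset[str] = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "genes", frozenset(v.gene for v in self.variants)
        )

    def variants_for(self, gene: str) -> tuple[PanelVariant, ...]:
        gene = gene.upper()
        return tuple(v for v in self.variants if v.gene == gene)

    def protein_keys(self) -> frozenset[tuple[str, str]]:
        """(gene, short-form protein key) pairs over entries carrying protein forms."""
        return frozenset(
            (v.gene, canonical_key(v.descriptor, "protein").key_text)
            for v in self.variants
            if v.descriptor.protein is not None
        )

    def cdna_keys(self) -> frozenset[tuple[str, str]]:
        return frozenset(
            (v.gene, canonical_key(v.descriptor, "cdna").key_text)
            for v in self.variants
            if v.descriptor.cdna is not None
        )


def default_panel_path() -> Path:
    """Path of the panel definition shipped with the package.

    The shipped file is a synthetic best-effort reconstruction of a
    four-cartridge BRAF/EGFR/KRAS/NRAS hotspot panel assembled from public
    vendor technical-sheet content; any user-supplied panel file in the same
    schema is equally valid everywhere a panel is accepted.
    """
    return Path(str(resources.files("panelscope.data") / "idylla_panel_v1.tsv"))


def _rows_from_tsv(path: Path) -> list[dict[str, str]]:
    lines = path.read_text(encoding="utf-8").splitlines()
    lines = [ln for ln in lines if ln.strip() and not ln.startswith("#")]
    if not lines:
        return []
    header = [h.strip() for h in lines[0].split("\t")]
    missing = [c for c in _COLUMNS if c not in header]
    if missing:
        raise PanelLoadError(f"panel TSV missing columns {missing}; found {header}")
    rows = []
    for ln in lines[1:]:
        cells = ln.split("\t")
        cells += [""] * (len(header) - len(cells))
        rows.append({h: c.strip() for h, c in zip(header, cells)})
    return rows


def _rows_from_json(path: Path) -> list[dict[str, str]]:
    data = json.loads(path.read_text(encoding="utf-8"))
    if not isinstance(data, list):
        raise PanelLoadError("panel JSON must be an array of row objects")
    return [{c: str(row.get(c, "") or "").strip() for c in _COLUMNS} for row in data]


def load_panel(path: str | Path, *, name: str | None = None,
               version: str = "0", strict: bool = True) -> PanelDefinition:
    """Load and validate a panel-definition file (TSV or JSON).

    Every row is parsed through the variant-name grammar; a row that fails to
    parse raises :class:`PanelLoadError` naming the row number. Two rows that
    collapse to the same (gene, canonical protein key) are a validation error
    in ``strict`` mode (the default) and are silently collapsed to the first
    occurrence otherwise. Row order is preserved.
    """
    path = Path(path)
    if not path.exists():
        raise PanelLoadError(f"panel file not found: {path}")
    rows = (
        _rows_from_json(path)
        if path.suffix.lower() == ".json"
        else _rows_from_tsv(path)
    )
    variants: list[PanelVariant] = []
    seen_protein: dict[tuple[str, str], int] = {}
    seen_cdna_only: dict[tuple[str, str], int] = {}
    for i, row in enumerate(rows, start=2):  # 1-based, after header
        gene = row["gene"].upper()
        if not gene:
            raise PanelLoadError(f"panel row {i}: empty gene symbol")
        cdna = protein = None
        try:
            if row["cdna"]:
                cdna = parse_cdna(row["cdna"])
            if row["protein"]:
                protein = parse_protein(row["protein"])
        except ParseError as exc:
            raise PanelLoadError(f"panel row {i}: {exc}") from exc
        if cdna is None and protein is None:
            raise PanelLoadError(f"panel row {i}: neither cdna nor protein given")
        descriptor = VariantDescriptor(gene=gene, cdna=cdna, protein=protein)
        variant = PanelVariant(
            gene=gene,
            descriptor=descriptor,
            vendor_label=row["vendor_label"],
            variant_class=row["class"] or "snv",
            cartridge=row["cartridge"],
        )
        if protein is not None:
            key = (gene, protein.short_form())
            dup_row = seen_protein.get(key)
            seen = seen_protein
        else:
            key = (gene, cdna.key_text())  # type: ignore[union-attr]
            dup_row = seen_cdna_only.get(key)
            seen = seen_cdna_only
        if dup_row is not None:
            if strict:
                raise PanelLoadError(
                    f"panel row {i}: duplicate canonical key {key} (first seen row {dup_row})"
                )
            continue
        seen[key] = i
        variants.append(variant)
    return PanelDefinition(
        name=name or path.stem, version=version, variants=tuple(variants)
    )


def panel_summary(panel: PanelDefinition):
    """Per-gene variant counts as a DataFrame: (gene, n_variants, n_snv, n_indel)."""
    import pandas as pd

    rows = []
    for gene in sorted(panel.genes):
        vs = panel.variants_for(gene)
        n_snv = sum(1 for v in vs if v.variant_class == "snv")
        rows.append(
            {"gene": gene, "n_variants": len(vs), "n_snv": n_snv, "n_indel": len(vs) - n_snv}
        )
    return pd.DataFrame(rows, columns=["gene", "n_variants", "n_snv", "n_indel"])


def contains(panel: PanelDefinition, descriptor: VariantDescriptor):
    """Match one descriptor against the panel; returns a coverage MatchResult.

    Thin wrapper over the per-record matcher in :mod:`panelscope.coverage`,
    kept here so panel-centric code can ask membership questions directly.
    """
    from panelscope.coverage import match_descriptor

    return match_descriptor(descriptor, panel)
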