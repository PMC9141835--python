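"""Seeded, truth-labelled synthetic cohorts.

Clinical mutation cohorts of the kind this package analyses are rarely
shareable (patient consent does not extend to raw sequencing data), so every
pipeline stage here is exercised against generated cohorts instead. The
generator emulates the structure that matters to the analysis:

* strata of (gene, diagnosis) cases with a controlled number — or binomial
  fraction — of panel-detectable index mutations;
* a tier composition, either drawn from weights or fixed exactly per tier;
* co-occurring "extra" mutations (optionally high-tier and undetectable),
  the structure behind the extra-mutation columns of disease-concordance
  tables;
* duplicate export rows, to exercise deduplication;
* a mix of name dialects (cDNA only, long protein, short protein, or all
  columns populated), to exercise the parser and representation matching.

Two sampling modes exist deliberately. Exact-count mode lays the composition
down deterministically — printed summary tables are exact compositions, not
draws, so reconstructing one must not depend on sampling noise. Fraction mode
draws Bernoulli detectability and is what statistical property tests use.

Every generated record gets a truth label; the analysis pipeline is expected
to reproduce the labels with zero discordance in exact-count mode.

Determinism: one global seed; each stratum derives an independent substream
from a stable hash of (gene, diagnosis), so adding a stratum never perturbs
the records of another.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from panelscope.cohort_io import CohortRecord, CohortTable, TIERS
from panelscope.hgvs_core import (
    AA_1TO3,
    ProteinChange,
    ProteinKind,
    VariantDescriptor,
    parse_cdna,
    parse_protein,
)
from panelscope.panel_registry import PanelDefinition

__all__ = [
    "DIALECTS",
    "SpecError",
    "GenerationError",
    "StratumSpec",
    "TruthLabel",
    "generate_cohort",
    "generate_raw_rows",
    "generate_nonpanel_variant",
    "write_truth",
    "read_truth",
    "annotations_frame",
    "load_stratum_specs",
]

DIALECTS = ("cdna_only", "long_protein", "short_protein", "all_three")

# genes seen as co-occurring extra mutations but absent from the panel
_EXTRA_GENES = ("PIK3CA", "MAP2K1", "TET2", "SF3B1", "IDH1", "TP53")

_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
_BASES = "ACGT"


class SpecError(ValueError):
    """A stratum specification is internally inconsistent or names an unknown gene."""


class GenerationError(RuntimeError):
    """The generator could not satisfy a constraint (pathological panels)."""


@dataclass(frozen=True)
class StratumSpec:
    """One (gene, diagnosis) stratum of the simulated cohort.

    Detectability is given either exactly (``n_detectable``) or as a
    Bernoulli ``detectable_fraction`` — exactly one of the two. The optional
    ``tier_plan`` fixes the joint tier x detectable composition exactly as a
    list of ``(tier, n, n_detectable)`` triples; without it, exact mode
    assigns Tier 1 to detectable and Tier 3 to non-detectable index
    mutations, and fraction mode draws tiers from ``tier_weights``.
    ``n_extra``/``n_extra_high`` fix extra-mutation counts exactly;
    ``p_extra_mutation``/``p_extra_high_tier_undetected`` are their
    stochastic counterparts (the latter conditional on having an extra).
    """

    gene: str
    diagnosis: str
    n_cases: int
    n_detectable: int | None = None
    detectable_fraction: float | None = None
    tier_plan: tuple[tuple[str, int, int], ...] | None = None
    tier_weights: dict = field(
        default_factory=lambda: {"1": 0.85, "2": 0.05, "3": 0.10}
    )
    n_extra: int | None = None
    n_extra_high: int | None = None
    p_extra_mutation: float = 0.0
    p_extra_high_tier_undetected: float = 0.0
    duplicate_rate: float = 0.0
    name_dialect_mix: dict = field(
        default_factory=lambda: {
            "all_three": 0.55, "short_protein": 0.20, "long_protein": 0.15, "cdna_only": 0.10,
        }
    )
    study_id: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene", self.gene.strip().upper())
        if self.n_cases < 0:
            raise SpecError("n_cases must be >= 0")
        if (self.n_detectable is None) == (self.detectable_fraction is None):
            raise SpecError(
                f"stratum ({self.gene}, {self.diagnosis}): give exactly one of "
                "n_detectable / detectable_fraction"
            )
        if self.n_detectable is not None and not 0 <= self.n_detectable <= self.n_cases:
            raise SpecError("n_detectable must lie in [0, n_cases]")
        for name in ("detectable_fraction", "p_extra_mutation",
                     "p_extra_high_tier_undetected", "duplicate_rate"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise SpecError(f"{name} must be a probability, got {v}")
        for weights, what in ((self.tier_weights, "tier_weights"),
                              (self.name_dialect_mix, "name_dialect_mix")):
            if abs(sum(weights.values()) - 1.0) > 1e-9:
                raise SpecError(f"{what} must sum to 1")
        for tier in self.tier_weights:
            if tier not in TIERS:
                raise SpecError(f"unknown tier {tier!r}")
        for dialect in self.name_dialect_mix:
            if dialect not in DIALECTS:
                raise SpecError(f"unknown name dialect {dialect!r}")
        if self.tier_plan is not None:
            if self.n_detectable is None:
                raise SpecError("tier_plan requires exact-count mode")
            object.__setattr__(
                self, "tier_plan", tuple((str(t), int(n), int(d)) for t, n, d in self.tier_plan)
            )
            if sum(n for _, n, _ in self.tier_plan) != self.n_cases:
                raise SpecError("tier_plan case counts must sum to n_cases")
            if sum(d for _, _, d in self.tier_plan) != self.n_detectable:
                raise SpecError("tier_plan detectable counts must sum to n_detectable")
            for t, n, d in self.tier_plan:
                if t not in TIERS or d > n:
                    raise SpecError(f"bad tier_plan entry {(t, n, d)}")
        if self.n_extra is not None and self.n_extra > self.n_cases:
            raise SpecError("n_extra must be <= n_cases")
        if self.n_extra_high is not None:
            if self.n_extra is None or self.n_extra_high > self.n_extra:
                raise SpecError("n_extra_high requires n_extra and must be <= it")

    @property
    def default_study_id(self) -> str:
        return self.study_id or f"synthetic-{self.gene}-{self.diagnosis.replace(' ', '_')}"


@dataclass(frozen=True)
class TruthLabel:
    """Ground truth for one generated (unique) record."""

    sample_key: str
    record_index: int
    gene: str
    is_panel_detectable: bool
    is_extra: bool
    tier: str


def _stratum_rng(seed: int, spec: StratumSpec) -> np.random.Generator:
    sub = zlib.crc32(f"{spec.gene}|{spec.diagnosis}".encode("utf-8"))
    return np.random.default_rng([int(seed), sub])


def generate_nonpanel_variant(
    gene: str, panel: PanelDefinition, rng: np.random.Generator
) -> VariantDescriptor:
    """A realistic-looking variant whose canonical keys are absent from the panel.

    Emits missense, nonsense or frameshift events (real-looking positions and
    alleles rather than random strings, so the parser surface is exercised),
    always carrying both a cDNA and a protein form, and retries until both
    canonical keys are disjoint from the panel's key sets.
    """
    gene = gene.upper()
    protein_keys = panel.protein_keys()
    cdna_keys = panel.cdna_keys()
    for _ in range(200):
        pos = int(rng.integers(5, 900))
        ref = _RESIDUES[int(rng.integers(len(_RESIDUES)))]
        roll = rng.random()
        if roll < 0.8:
            alt = _RESIDUES[int(rng.integers(len(_RESIDUES)))]
            if alt == ref:
                continue
            short = f"p.{ref}{pos}{alt}"
        elif roll < 0.9:
            short = f"p.{ref}{pos}*"
        else:
            short = f"p.{ref}{pos}fs"
        base_pos = 3 * pos - int(rng.integers(0, 3))
        b_ref = _BASES[int(rng.integers(4))]
        b_alt = _BASES[int(rng.integers(4))]
        if b_ref == b_alt:
            continue
        cdna_text = f"c.{base_pos}{b_ref}>{b_alt}"
        protein = parse_protein(short)
        cdna = parse_cdna(cdna_text)
        if (gene, protein.short_form()) in protein_keys:
            continue
        if (gene, cdna.key_text()) in cdna_keys:
            continue
        return VariantDescriptor(gene=gene, cdna=cdna, protein=protein)
    raise GenerationError(
        f"could not generate a variant of {gene} disjoint from the panel after 200 attempts"
    )


def _long_form_text(protein: ProteinChange) -> str:
    return protein.long_form()


def _raw_names_for(descriptor: VariantDescriptor, dialect: str) -> tuple[str, str, str]:
    """(cdna, long, short) cells for the chosen dialect, constrained to the
    representations the descriptor actually carries."""
    has_c = descriptor.cdna is not None
    has_p = descriptor.protein is not None
    if dialect == "cdna_only" and not has_c:
        dialect = "short_protein"
    if dialect in ("long_protein", "short_protein") and not has_p:
        dialect = "cdna_only"
    cdna_text = descriptor.cdna.format() if has_c else ""
    long_text = _long_form_text(descriptor.protein) if has_p else ""
    short_text = descriptor.protein.short_form() if has_p else ""
    if dialect == "cdna_only":
        return (cdna_text, "", "")
    if dialect == "long_protein":
        return ("", long_text, "")
    if dialect == "short_protein":
        return ("", "", short_text)
    return (cdna_text, long_text, short_text)


def _pick(rng: np.random.Generator, weights: dict) -> str:
    keys = sorted(weights)  # sorted for cross-run stability
    probs = np.array([weights[k] for k in keys], dtype=float)
    return keys[int(rng.choice(len(keys), p=probs / probs.sum()))]


def _tier_sequence(spec: StratumSpec, detect_flags: list[bool]) -> list[str]:
    if spec.tier_plan is not None:
        det_pool: list[str] = []
        non_pool: list[str] = []
        for tier, n, d in spec.tier_plan:
            det_pool += [tier] * d
            non_pool += [tier] * (n - d)
        det_iter, non_iter = iter(det_pool), iter(non_pool)
        return [next(det_iter) if f else next(non_iter) for f in detect_flags]
    if spec.n_detectable is not None:
        # exact mode default: detectable index mutations are the actionable
        # (Tier 1) ones; the panel-missed remainder is Tier 3
        return ["1" if f else "3" for f in detect_flags]
    return []  # fraction mode draws per record


def generate_raw_rows(
    specs: list[StratumSpec], panel: PanelDefinition, seed: int
) -> tuple[list[CohortRecord], list[TruthLabel]]:
    """Generate export rows including duplicates, plus per-unique-record truth.

    The returned row list is what a raw export file would contain (duplicate
    rows included, in generation order); the labels cover the unique records
    only, in the order deduplication preserves them.
    """
    for spec in specs:
        if spec.gene not in panel.genes:
            raise SpecError(
                f"stratum ({spec.gene}, {spec.diagnosis}): gene absent from panel "
                f"{sorted(panel.genes)}"
            )

    rows: list[CohortRecord] = []
    labels: list[TruthLabel] = []
    index = 0
    for spec in specs:
        rng = _stratum_rng(seed, spec)
        panel_variants = panel.variants_for(spec.gene)
        if spec.n_detectable is not None:
            detect_flags = [i < spec.n_detectable for i in range(spec.n_cases)]
        else:
            detect_flags = list(rng.random(spec.n_cases) < spec.detectable_fraction)
        tiers = _tier_sequence(spec, detect_flags)

        if spec.n_extra is not None:
            extra_flags = [i < spec.n_extra for i in range(spec.n_cases)]
            n_high = spec.n_extra_high or 0
            extra_high_flags = [i < n_high for i in range(spec.n_cases)]
        else:
            extra_flags = list(rng.random(spec.n_cases) < spec.p_extra_mutation)
            extra_high_flags = [
                bool(e) and (rng.random() < spec.p_extra_high_tier_undetected)
                for e in extra_flags
            ]

        for i in range(spec.n_cases):
            sample_id = f"S{i:05d}"
            detectable = bool(detect_flags[i])
            if detectable:
                descriptor = panel_variants[int(rng.integers(len(panel_variants)))].descriptor
            else:
                descriptor = generate_nonpanel_variant(spec.gene, panel, rng)
            tier = tiers[i] if tiers else _pick(rng, spec.tier_weights)
            dialect = _pick(rng, spec.name_dialect_mix)
            record = CohortRecord(
                study_id=spec.default_study_id,
                sample_id=sample_id,
                gene=spec.gene,
                descriptor=descriptor,
                raw_names=_raw_names_for(descriptor, dialect),
                tier=tier,
                diagnosis=spec.diagnosis,
            )
            rows.append(record)
            labels.append(
                TruthLabel(record.sample_key, index, spec.gene, detectable, False, tier)
            )
            index += 1
            if rng.random() < spec.duplicate_rate:
                rows.append(record)  # exact duplicate export row; dedup removes it

            if extra_flags[i]:
                high = bool(extra_high_flags[i])
                # exact mode keeps extras on off-panel genes so one sample never
                # carries two same-gene records with different tiers (which would
                # make a gene-keyed tier annotation ambiguous); fraction mode
                # also emits same-gene second hits for realism
                if spec.n_extra is not None or high or rng.random() < 0.7:
                    extra_gene = _EXTRA_GENES[int(rng.integers(len(_EXTRA_GENES)))]
                else:
                    extra_gene = spec.gene
                extra_descriptor = generate_nonpanel_variant(extra_gene, panel, rng)
                extra_tier = "1" if high else "3"
                extra_record = CohortRecord(
                    study_id=spec.default_study_id,
                    sample_id=sample_id,
                    gene=extra_gene,
                    descriptor=extra_descriptor,
                    raw_names=_raw_names_for(extra_descriptor, _pick(rng, spec.name_dialect_mix)),
                    tier=extra_tier,
                    diagnosis=spec.diagnosis,
                )
                rows.append(extra_record)
                labels.append(
                    TruthLabel(extra_record.sample_key, index, extra_gene, False, True, extra_tier)
                )
                index += 1
    return rows, labels


def generate_cohort(
    specs: list[StratumSpec], panel: PanelDefinition, seed: int
) -> tuple[CohortTable, list[TruthLabel]]:
    """Deduplicated cohort table plus one truth label per record.

    A fixed seed yields identical output across runs and platforms. The
    table's provenance records the duplicate rows generated and removed.
    """
    rows, labels = generate_raw_rows(specs, panel, seed)
    seen: set[int] = set()
    unique: list[CohortRecord] = []
    for r in rows:
        key = id(r)  # duplicates are literally the same object
        if key in seen:
            continue
        seen.add(key)
        unique.append(r)
    table = CohortTable((), ()).with_step("generate", len(rows), unique)
    if len(unique) != len(labels):
        raise AssertionError("one truth label per unique record expected")
    return table, labels


_TRUTH_COLUMNS = ["sample_key", "record_index", "gene", "is_panel_detectable", "is_extra", "tier"]


def write_truth(labels: list[TruthLabel], path: str | Path) -> None:
    """Write truth labels as TSV (lossless; see :func:`read_truth`)."""
    df = pd.DataFrame(
        [
            {
                "sample_key": l.sample_key,
                "record_index": l.record_index,
                "gene": l.gene,
                "is_panel_detectable": int(l.is_panel_detectable),
                "is_extra": int(l.is_extra),
                "tier": l.tier,
            }
            for l in labels
        ],
        columns=_TRUTH_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False, lineterminator="\n", encoding="utf-8")


def read_truth(path: str | Path) -> list[TruthLabel]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return [
        TruthLabel(
            sample_key=row["sample_key"],
            record_index=int(row["record_index"]),
            gene=row["gene"],
            is_panel_detectable=bool(int(row["is_panel_detectable"])),
            is_extra=bool(int(row["is_extra"])),
            tier=row["tier"],
        )
        for _, row in df.iterrows()
    ]


def annotations_frame(records) -> pd.DataFrame:
    """Tier/diagnosis side table (study_id, sample_id, gene, tier, diagnosis)
    for the generated records, ready for :func:`panelscope.cohort_io.attach_annotations`."""
    rows = [
        {
            "study_id": r.study_id,
            "sample_id": r.sample_id,
            "gene": r.gene,
            "tier": r.tier,
            "diagnosis": r.diagnosis or "",
        }
        for r in records
    ]
    return pd.DataFrame(rows).drop_duplicates().reset_index(drop=True)


def load_stratum_specs(path: str | Path) -> list[StratumSpec]:
    """Read a simulation spec file (YAML or JSON list of stratum mappings)."""
    import json

    path = Path(path)
    text = path.read_text(encoding="utf-8")
    data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    strata = data.get("strata") if isinstance(data, dict) else data
    if not isinstance(strata, list):
        raise SpecError(f"{path.name}: expected a list of strata")
    specs = []
    for raw in strata:
        if "tier_plan" in raw and raw["tier_plan"] is not None:
            raw = dict(raw)
            raw["tier_plan"] = tuple(tuple(entry) for entry in raw["tier_plan"])
        specs.append(StratumSpec(**raw))
    return specs
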