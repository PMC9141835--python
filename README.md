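# panelscope

Would a hotspot qPCR panel have caught your NGS-identified mutation?

Molecular pathology labs increasingly pair a slow-but-comprehensive NGS
workflow with a rapid cartridge-based allele-specific qPCR platform (e.g.
the Biocartis Idylla system) that detects a fixed list of *BRAF*, *EGFR*,
*KRAS* and *NRAS* hotspot mutations directly from FFPE sections.
`panelscope` audits that trade-off from the data a lab actually has — the
variant *names* in its NGS reports or a cBioPortal/MAF export, and the
assay's target list:

* a focused HGVS-subset parser canonicalises cDNA (`c.1799T>A`), long
  protein (`p.Val600Glu`) and short protein (`p.V600E`) spellings so every
  representation of one event collides on one key;
* every record is classified panel-detectable or not, with an auditable
  reason, against any panel-definition file (a reconstructed four-cartridge
  target set ships with the package);
* summaries mirror how such audits are reported: per-gene variant-level
  coverage, AMP/ASCO/CAP tier-stratified coverage, deduplicated
  unique-sample positivity, and per-disease case-level concordance with
  "extra mutation" columns (cases whose additional mutations — possibly in
  genes the cartridge cannot see — would have gone undetected);
* a rule engine encodes triage policy (cartridge first-line with
  reflex-to-NGS on a negative, orthogonal confirmation, straight to NGS);
* a seeded synthetic-cohort generator with truth labels makes every stage
  testable without access to patient data.

For the formal write-up of the matching semantics, summary definitions,
generator design and limitations, see [`docs/methods.md`](docs/methods.md);
the panel file schema is in [`docs/panel_format.md`](docs/panel_format.md).

## Worked example

Simulate a small melanoma/colorectal cohort against the shipped panel, then
summarize it:

```sh
cat > spec.yaml <<EOF
- {gene: BRAF, diagnosis: cutaneous melanoma, n_cases: 27, n_detectable: 21,
   n_extra: 8, n_extra_high: 2}
- {gene: KRAS, diagnosis: colorectal cancer, n_cases: 65, n_detectable: 62,
   n_extra: 24, n_extra_high: 17}
EOF
panelscope simulate --spec spec.yaml --seed 1 --out sim/
panelscope summarize --cohort sim/cohort.tsv --annotations sim/annotations.tsv \
    --genes BRAF,EGFR,KRAS,NRAS,PIK3CA,MAP2K1,TET2,SF3B1,IDH1,TP53 \
    --pairs "BRAF:cutaneous melanoma;KRAS:colorectal cancer" --out reports/
cat reports/concordance.md
```

which prints:

```
| Gene Mutation and Diagnosis | Case Numbers | Idylla Positive | Idylla Negative | Cases with Extra Mutations | Cases with Extra and High-Tier Mutations Not Detected |
| --- | --- | --- | --- | --- | --- |
| *BRAF* cutaneous melanoma | 27 | 21 (78%) | 6 (22%) | 8 (30%) | 2 (7%) |
| *KRAS* colorectal cancer | 65 | 62 (95%) | 3 (5%) | 24 (37%) | 17 (26%) |
```

Reading the *BRAF* row: of 27 melanoma cases carrying a *BRAF* mutation, the
cartridge would have called 21 (78%) positive; 8 cases (30%) carried
mutations beyond the index one, and in 2 (7%) an extra high-tier
(actionable) mutation would have gone undetected — cases where the rapid
result alone would be falsely reassuring. `reports/` also contains
gene-level, tier-level and per-sample TSVs (every percentage cell next to
its raw counts) and a `report.json` bundling all surfaces with the filter
provenance.

Triage a single question:

```sh
panelscope triage --tumor-type "cutaneous melanoma" --genes BRAF \
    --setting community_no_onsite_molecular
```

```json
{
  "modality": "idylla_first_line",
  "reflex": "reflex_to_ngs_if_negative",
  "rationale": "Pathologists in smaller and/or rural hospitals without an on-site molecular laboratory can run the fully automated cartridge on FFPE sections directly; if no mutation is identified, the sample is reflexed to send-out NGS testing.",
  "rule_id": "community-first-line"
}
```

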