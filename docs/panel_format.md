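# Panel-definition file format

A panel definition lists every variant an assay can detect, one concrete
variant per row. TSV and JSON carry identical fields.

## TSV

Tab-delimited, UTF-8, `#` lines are comments. Header row required:

| column | meaning |
| --- | --- |
| `gene` | uppercase gene symbol; must equal the descriptor's gene |
| `cdna` | coding-DNA name (`c.1799T>A`), or empty |
| `protein` | protein name, long or short form (`p.V600E`), or empty |
| `vendor_label` | the label the assay's documentation uses (`V600E2`) |
| `class` | `snv` or `indel` |
| `cartridge` | which cartridge/assay detects it (`NRAS-BRAF`) |

At least one of `cdna`/`protein` must be non-empty per row. Rows keep file
order; matching returns the first matching row.

## JSON

An array of objects with the same six field names; missing or null fields
are treated as empty.

## Validation rules

* every name must parse under the supported grammar — a failing row aborts
  the load with its row number;
* no two rows may share the same (gene, canonical protein key): a strict
  load (the default) raises, a lenient load keeps the first row;
* rows carrying only a cDNA name are deduplicated on (gene, cDNA key).

## Authoring conventions

Expand grouped vendor labels to one row per concrete change. When two codon
changes produce the same protein change (e.g. V600E and V600E2), give the
second row the cDNA form only — it stays matchable at the cDNA level without
violating protein-key uniqueness.

## The shipped fixture

`panelscope/data/idylla_panel_v1.tsv` is a **synthetic reconstruction** of a
four-cartridge BRAF/EGFR/KRAS/NRAS hotspot target set, assembled from
publicly stated cartridge content (BRAF codon 600; KRAS codons
12/13/59/61/117/146; NRAS codons 12/13/59/61; EGFR exon 18–21 point
mutations, exon 19 deletions, exon 20 insertions), 72 concrete variants in
total under the expansion convention above. It is not a vendor package
insert and its row count is a convention, not the insert's advertised
target count. Every command and function accepts `--panel`/`panel=` with a
user file in this schema; use the real insert for assay-exact analysis.
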