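# Methods

## The question

Cartridge-based allele-specific qPCR platforms (the Biocartis Idylla system
being the canonical example) detect a fixed, vendor-published list of hotspot
mutations in *BRAF*, *EGFR*, *KRAS* and *NRAS* directly from FFPE sections,
with automated interpretation and same-day turnaround. NGS panels detect far
more but are slower and need specialised staff. The operational question for
a molecular lab is: *of the mutations our NGS workflow actually reports, what
fraction would the cartridge have caught — overall, within clinically
actionable tiers, per disease, and per patient?* `panelscope` answers that by
string-level matching of variant names against a panel definition, followed
by deduplicated counting, which is exactly how such concordance audits are
done in practice (the inputs are name columns of exports and package inserts,
not aligned reads).

## Variant-name matching

Cohort exports name one event up to three ways: a coding-DNA change
(`c.1799T>A`), a long protein form (`p.Val600Glu`) and a short protein form
(`p.V600E`). The matcher canonicalises each representation:

* protein names parse into a representation-independent structure and render
  to a canonical one-letter short form; 3-letter and 1-letter spellings,
  optional `p.` prefix and HGVS predicted-consequence parentheses all
  collapse to one key;
* cDNA names normalise case and drop bases that are redundant given the
  position range (`c.2235_2249delTTAAG…` keys equal to `c.2235_2249del`);
* frameshifts canonicalise to residue+position+`fs`, discarding extension
  lengths (`fs*12`), because assay target lists spell frameshifts without
  them and keeping them would only manufacture false mismatches.

Two descriptors of the same gene are the same variant if their protein keys
agree; the protein level is *decisive* whenever both sides carry it, and the
cDNA level is consulted otherwise. A record sharing no representation level
with a panel entry is indeterminate and is counted **not detectable**, with
the reason recorded — conservative and auditable. No transcript-aware
normalisation (3′-shifting, reference checks) is attempted: the inputs are
exported name strings, and introducing reference lookups would change the
tool from an export auditor into an annotation pipeline.

## Panel definitions

A panel is an ordered list of single concrete variants (TSV or JSON; see
`docs/panel_format.md`). Grouped vendor labels ("V600E/E2/D") must be
expanded at file-authoring time, one row per concrete change; a row whose
protein change duplicates an earlier row (an alternative codon change such as
V600E2) carries the cDNA form only, which also preserves the invariant that
no two rows share a (gene, protein-key) pair. The shipped
`idylla_panel_v1.tsv` is a clearly-labelled synthetic reconstruction of a
four-cartridge target set assembled from public technical-sheet content
(72 concrete variants); it exists so every analysis and test runs without
downloads. Its variant count is therefore a counting convention, not the
vendor's insert count; assay-exact work should supply the real insert as a
panel file.

## Summary surfaces

* **Variant level** — per gene: records, detectable records, percentage; tier
  and diagnosis breakdowns. Genes with zero records are omitted, never 0/0.
* **Tier-stratified** — coverage within each AMP/ASCO/CAP tier; tiers are
  consumed as input annotations (this package never assigns them).
* **Sample level** — records group by a `study‖sample` key (explicit
  separator, so `("ab","c")` and `("a","bc")` cannot collide); each unique
  sample counts once, so a specimen with two detectable mutations is one
  positive.
* **Disease concordance** — per (index gene, diagnosis) pair: a case is a
  unique sample with ≥ 1 index-gene record and that diagnosis; positive if
  any index-gene record matches. Extra-mutation columns look across **all**
  the sample's records regardless of gene: `n_extra` counts cases with any
  record beyond the index mutation, and `n_extra_high_tier` counts cases
  with an extra record **and** ≥ 1 high-tier record (Tier 1/2 by default,
  configurable) the panel would not detect. The two-condition reading is a
  deliberate design choice: the single column header such tables print
  conflates "has extras" with "misses something actionable", and the
  conjunction is the clinically meaningful event (the cartridge result alone
  would have been falsely reassuring).

Percentages render with round-half-up at 0 or 1 decimals — the convention
clinical tables use — and every percentage in TSV output sits next to its raw
numerator/denominator. Division by zero is an error at the formatting layer;
callers suppress the row.

## Duplicate and dedup semantics

A duplicate is byte-equality of all six retained export columns after
whitespace trimming — the least destructive reading of "duplicates were
filtered"; two records of the same sample with different name spellings are
*not* merged. Every filter step appends (step, rows-in, rows-out) to the
table's provenance, so conservation is checkable after the fact. Rows whose
names all fail the grammar are kept, flagged non-canonical, and classified
not-detectable with reason "unparsable variant name" rather than silently
dropped.

## Triage rules

The rule engine is an ordered first-match-wins list over a closed context
vocabulary (tumor type, genes in question, care setting, tissue adequacy,
urgency, prior result), with a mandatory unconditional terminal rule, so
totality is a validation property rather than a hope. The shipped default
encodes only well-supported practice points: scant tissue → NGS; off-panel
gene → NGS; ambiguous prior NGS result → cartridge as orthogonal
confirmation; community setting without on-site molecular lab → cartridge
first-line with reflex-to-NGS on a negative; urgent single-gene questions at
NGS-capable centers → cartridge first with reflex; otherwise NGS. Finer
branch structure is genuinely site-specific and is left to user rulesets.

## Synthetic cohorts

The clinical and portal cohorts behind published concordance tables are not
shareable, so the generator emulates their structure: per-(gene, diagnosis)
strata with controlled detectable counts, tier composition, co-occurring
extra mutations, duplicate export rows, and a mix of name dialects
(cDNA-only, long protein, short protein, all three). Detectable records draw
uniformly from the panel's entries for the gene; non-detectable records are
perturbed realistic events (missense/nonsense/frameshift at plausible
positions) whose canonical keys are verified disjoint from the panel at both
levels. Default dialect mix is 55% all-three, 20% short-only, 15% long-only,
10% cDNA-only, roughly the column-population pattern of portal exports.

Two sampling modes, deliberately:

* **exact-count** — the composition is laid down deterministically (first
  *k* of *n* cases detectable, tiers per an explicit per-tier plan or Tier 1
  for detectable / Tier 3 for the remainder, extras on off-panel genes so a
  gene-keyed tier annotation stays unambiguous). Printed summary tables are
  exact compositions, not draws; reconstruction must not depend on sampling
  noise.
* **fraction** — Bernoulli detectability, weighted tiers, probabilistic
  extras (including same-gene second hits). Used for statistical property
  checks such as recovering a 0.85 detectable fraction at n = 2000 within
  the exact central 99% binomial interval.

One global seed; each stratum derives its RNG substream from a CRC32 hash of
(gene, diagnosis), so adding a stratum never perturbs another's records.

What passing the reconstruction checks shows — and does not. The generator
produces name strings the parser fully understands (plus controlled
unparsable-row tests), exact duplicates only, and per-sample-consistent
annotations. Real exports contain dialect quirks beyond the supported
grammar (intronic and splice names, allele syntax), near-duplicate rows that
differ in irrelevant columns, and annotation conflicts; the pipeline
surfaces these as flagged records or errors, but the reconstruction numbers
say nothing about their frequency in any real cohort. Matching is also only
as good as the panel file: it audits name agreement, not assay chemistry
(limit of detection and low-VAF dropout are explicitly out of scope).

## Reference compositions and problem sizes

`panelscope.compositions` encodes a published four-gene concordance study's
printed table compositions as generator strata: variant-level strata of
159/133/303/96 records with exact tier×detectable plans, a portal-aggregate
sample-level composition of 11 746 samples, and eight disease strata of
3–158 cases with exact extras counts. `run_reconstruction` pushes each
through the file-level pipeline (write TSV → re-read/parse → dedup → gene
filter or annotation join → classify → summarize); the whole reconstruction
takes a few seconds on one CPU. The property suites run at 10 400 records
(matcher-vs-oracle), 20 × 2000 (parameter recovery) and 200 small random
cohorts (conservation/permutation) — sizes chosen so the complete test suite
finishes in well under a minute while keeping every check statistically
meaningful.

## Known limitations

* HGVS coverage is the coding/protein subset that appears in hotspot lists
  and exports; intronic, UTR, splice, genomic (`g.`) and allele syntax are
  rejected (flagged non-canonical, never guessed at).
* Indels compare as normalised text; two genuinely different spellings of
  one indel event (e.g. un-shifted vs 3′-shifted coordinates) will not
  match. Panel files should use the spelling convention of the cohort
  source, or list both.
* Tiers and diagnoses are inputs; no tiering algorithm is included.
* No statistical testing of concordance (no kappa, no CIs) — the surfaces
  are descriptive counts, as in the audits they mirror.
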