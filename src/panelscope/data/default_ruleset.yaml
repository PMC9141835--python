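# Default triage ruleset. Ordered; first match wins; the last rule is the
# mandatory unconditional default. Each rationale is the practice point the
# rule encodes, so every recommendation is auditable back to its reason.
#
# Branch structure beyond these practice points (e.g. whether urgency alone
# should trigger cartridge-first testing at academic centers) is a judgment
# call; sites with different workflows should ship their own ruleset file.
rules:
  - rule_id: scant-tissue-ngs
    match:
      tissue_adequacy: scant
    action:
      modality: ngs_first
      reflex: none
    rationale: >-
      Scant tissue samples may necessitate conventional NGS protocols; the
      cartridge consumes whole FFPE sections and cannot be re-queued across
      additional gene panels.

  - rule_id: off-panel-gene-ngs
    match:
      genes_on_panel: false
    action:
      modality: ngs_first
      reflex: none
    rationale: >-
      At least one gene in question is outside the four-gene hotspot panel
      (BRAF, EGFR, KRAS, NRAS); only sequencing can interrogate it.

  - rule_id: orthogonal-confirmation
    match:
      prior_result: ngs_ambiguous
    action:
      modality: idylla_orthogonal_confirmation
      reflex: none
    rationale: >-
      The rapid qPCR assay can be used for orthogonal confirmation of
      ambiguous results from other (NGS) testing methods.

  - rule_id: community-first-line
    match:
      care_setting: community_no_onsite_molecular
    action:
      modality: idylla_first_line
      reflex: reflex_to_ngs_if_negative
    rationale: >-
      Pathologists in smaller and/or rural hospitals without an on-site
      molecular laboratory can run the fully automated cartridge on FFPE
      sections directly; if no mutation is identified, the sample is
      reflexed to send-out NGS testing.

  - rule_id: academic-urgent-single-gene
    match:
      care_setting: academic_with_ngs
      urgency: urgent
    action:
      modality: idylla_first_line
      reflex: reflex_to_ngs_if_negative
    rationale: >-
      At centers with NGS capability the cartridge still wins on-demand
      single-gene situations where rapid identification of a BRAF, NRAS,
      KRAS or EGFR mutation is needed for diagnosis or to start targeted
      therapy; a negative reflexes to the routine NGS workflow.

  - rule_id: default-ngs
    action:
      modality: ngs_first
      reflex: none
    rationale: >-
      Routine testing at a center with sequencing capability: NGS remains
      the gold standard and covers mutations beyond the hotspot lists.
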