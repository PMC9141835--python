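# Errata in the reference summaries

The reference study's printed tables are the compositions
`panelscope.compositions` encodes. A few printed percentages are not
consistent with their own printed counts under any rounding convention (the
counts themselves are internally consistent and are what the reconstruction
asserts). Catalogued here so no check silently "validates" a typo; the
package reports the count-derived value in every case.

| where | printed | count-derived (round-half-up) |
| --- | --- | --- |
| BRAF Tier 1 share of variants | 93% (147 of 159) | 92% |
| EGFR variants detectable | 78% (76 of 96) | 79% |
| BRAF-melanoma extras (narrative) | "Eight (33%)" | 8/27 = 30% (table agrees) |
| BRAF-melanoma extra + high-tier undetected | 2 (8%) | 2/27 = 7% |
| NRAS-CRC row (all three percentages) | 66% / 33% / 66% | 67% / 33% / 67% (row is truncated, not rounded) |
| EGFR-lung negatives | 9 (7%) | 9/65 = 14% (count 9 = 65 − 56 is consistent) |
| KRAS-lung extras (narrative) | "Twenty-five (13%)" | 25/158 = 16% (table agrees) |

Every other printed percentage in the reference summaries reproduces exactly
under round-half-up at its printed precision; the full list is asserted in
the test suite.
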