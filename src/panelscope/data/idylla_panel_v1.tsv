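# Synthetic reconstruction of a four-cartridge BRAF/EGFR/KRAS/NRAS hotspot-qPCR
# detectable-variant list, assembled from publicly stated cartridge target content
# (codons 600 for BRAF; 12/13/59/61/117/146 for KRAS; 12/13/59/61 for NRAS; EGFR
# exon 18-21 hotspots, exon 19 deletions and exon 20 insertions). Grouped vendor
# labels are expanded to one row per concrete variant; rows whose protein change
# duplicates an earlier row (alternative codon changes) carry the cDNA form only.
# This file is NOT the vendor's package insert and ships only so analyses run
# download-free; point --panel at your own file for assay-exact work.
gene	cdna	protein	vendor_label	class	cartridge
BRAF	c.1799T>A	p.V600E	V600E	snv	BRAF
BRAF	c.1799_1800delinsAA		V600E2	snv	BRAF
BRAF	c.1799_1800delinsAT	p.V600D	V600D	snv	BRAF
BRAF	c.1798_1799delinsAA	p.V600K	V600K	snv	BRAF
BRAF	c.1798_1799delinsAG	p.V600R	V600R	snv	BRAF
BRAF	c.1798G>A	p.V600M	V600M	snv	BRAF
NRAS	c.35G>C	p.G12A	G12A	snv	NRAS-BRAF
NRAS	c.34G>T	p.G12C	G12C	snv	NRAS-BRAF
NRAS	c.35G>A	p.G12D	G12D	snv	NRAS-BRAF
NRAS	c.34G>A	p.G12S	G12S	snv	NRAS-BRAF
NRAS	c.35G>T	p.G12V	G12V	snv	NRAS-BRAF
NRAS	c.38G>C	p.G13A	G13A	snv	NRAS-BRAF
NRAS	c.37G>T	p.G13C	G13C	snv	NRAS-BRAF
NRAS	c.38G>A	p.G13D	G13D	snv	NRAS-BRAF
NRAS	c.37G>C	p.G13R	G13R	snv	NRAS-BRAF
NRAS	c.37G>A	p.G13S	G13S	snv	NRAS-BRAF
NRAS	c.38G>T	p.G13V	G13V	snv	NRAS-BRAF
NRAS	c.176C>A	p.A59D	A59D	snv	NRAS-BRAF
NRAS	c.175G>A	p.A59T	A59T	snv	NRAS-BRAF
NRAS	c.181C>G	p.Q61E	Q61E	snv	NRAS-BRAF
NRAS		p.Q61H	Q61H	snv	NRAS-BRAF
NRAS	c.181C>A	p.Q61K	Q61K	snv	NRAS-BRAF
NRAS	c.182A>T	p.Q61L	Q61L	snv	NRAS-BRAF
NRAS	c.182A>C	p.Q61P	Q61P	snv	NRAS-BRAF
NRAS	c.182A>G	p.Q61R	Q61R	snv	NRAS-BRAF
KRAS	c.35G>C	p.G12A	G12A	snv	KRAS
KRAS	c.34G>T	p.G12C	G12C	snv	KRAS
KRAS	c.35G>A	p.G12D	G12D	snv	KRAS
KRAS	c.34G>C	p.G12R	G12R	snv	KRAS
KRAS	c.34G>A	p.G12S	G12S	snv	KRAS
KRAS	c.35G>T	p.G12V	G12V	snv	KRAS
KRAS	c.37G>T	p.G13C	G13C	snv	KRAS
KRAS	c.38G>A	p.G13D	G13D	snv	KRAS
KRAS	c.176C>A	p.A59E	A59E	snv	KRAS
KRAS	c.176C>G	p.A59G	A59G	snv	KRAS
KRAS	c.175G>A	p.A59T	A59T	snv	KRAS
KRAS	c.181C>G	p.Q61E	Q61E	snv	KRAS
KRAS		p.Q61H	Q61H	snv	KRAS
KRAS	c.181C>A	p.Q61K	Q61K	snv	KRAS
KRAS	c.182A>T	p.Q61L	Q61L	snv	KRAS
KRAS	c.182A>C	p.Q61P	Q61P	snv	KRAS
KRAS	c.182A>G	p.Q61R	Q61R	snv	KRAS
KRAS		p.K117N	K117N	snv	KRAS
KRAS	c.436G>C	p.A146P	A146P	snv	KRAS
KRAS	c.436G>A	p.A146T	A146T	snv	KRAS
KRAS	c.437C>T	p.A146V	A146V	snv	KRAS
EGFR	c.2156G>C	p.G719A	G719A	snv	EGFR
EGFR	c.2155G>T	p.G719C	G719C	snv	EGFR
EGFR	c.2155G>A	p.G719S	G719S	snv	EGFR
EGFR	c.2303G>T	p.S768I	S768I	snv	EGFR
EGFR	c.2369C>T	p.T790M	T790M	snv	EGFR
EGFR	c.2573T>G	p.L858R	L858R	snv	EGFR
EGFR	c.2582T>A	p.L861Q	L861Q	snv	EGFR
EGFR	c.2235_2249del	p.E746_A750del	Ex19del E746_A750	indel	EGFR
EGFR	c.2236_2250del		Ex19del E746_A750 (alt codon)	indel	EGFR
EGFR	c.2237_2255delinsT	p.E746_S752delinsV	Ex19del E746_S752>V	indel	EGFR
EGFR		p.E746_T751delinsA	Ex19del E746_T751>A	indel	EGFR
EGFR		p.E746_S752delinsD	Ex19del E746_S752>D	indel	EGFR
EGFR	c.2239_2248delinsC	p.L747_A750delinsP	Ex19del L747_A750>P	indel	EGFR
EGFR	c.2239_2253del	p.L747_T751del	Ex19del L747_T751	indel	EGFR
EGFR		p.L747_T751delinsP	Ex19del L747_T751>P	indel	EGFR
EGFR	c.2240_2257del	p.L747_P753delinsS	Ex19del L747_P753>S	indel	EGFR
EGFR	c.2239_2247del	p.L747_E749del	Ex19del L747_E749	indel	EGFR
EGFR		p.L747_S752del	Ex19del L747_S752	indel	EGFR
EGFR		p.E746_P753delinsVS	Ex19del E746_P753>VS	indel	EGFR
EGFR	c.2300_2308dup	p.A767_V769dup	Ex20ins A767_V769dup	indel	EGFR
EGFR		p.S768_D770dup	Ex20ins S768_D770dup	indel	EGFR
EGFR		p.D770_N771insSVD	Ex20ins D770_N771insSVD	indel	EGFR
EGFR		p.D770_N771insG	Ex20ins D770_N771insG	indel	EGFR
EGFR		p.V769_D770insASV	Ex20ins V769_D770insASV	indel	EGFR
EGFR		p.H773_V774insH	Ex20ins H773_V774insH	indel	EGFR
EGFR		p.H773_V774insNPH	Ex20ins H773_V774insNPH	indel	EGFR
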