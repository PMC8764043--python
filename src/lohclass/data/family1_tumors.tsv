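# Five tumors from family-1 carriers of BRCA1 c.4963T>C (p.Ser1655Pro),
# with pathologist-estimated viable tumor cellularity and measured VAF.
# Published values: cellularity 60/30/70/90/90 %, VAF 65/49/88/67/70 %.
# Patient 2 tumor 1 was measured by amplicon NGS; only its VAF (88%) was
# published, so the depths here are a synthetic rendering (88 alt of 100).
sample_id	variant_id	variant_class	effect	tissue	method	cellularity	germline_vaf	rep1	alt_depth	total_depth
P1-T1	c.4963T>C	VUS	MISSENSE	BREAST	PYRO	0.60	0.5	0.65
P1-T2	c.4963T>C	VUS	MISSENSE	BREAST	PYRO	0.30	0.5	0.49
P2-T1	c.4963T>C	VUS	MISSENSE	BREAST	NGS	0.70	0.5		88	100
P2-T2	c.4963T>C	VUS	MISSENSE	OVARY	PYRO	0.90	0.5	0.67
P3-T1	c.4963T>C	VUS	MISSENSE	BREAST	PYRO	0.90	0.5	0.70
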