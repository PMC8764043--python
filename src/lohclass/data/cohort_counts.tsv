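# Per-variant allelic-status counts for the 97-tumor reference cohort of
# BRCA1 germline-variant carriers (90 breast, 7 ovarian tumors; 26 variants).
# One row per variant x tissue. Counts are as published; two published
# percentage cells (c.5266dup, c.5324T>G) disagree with their own counts and
# are not encoded -- percentages are recomputed from counts downstream.
variant_id	hgvs_p	effect	classification	tissue	n_balance	n_loss_variant	n_loss_wt
c.68_69del	p.Glu23Valfs*17	FRAMESHIFT	PATHOGENIC	BREAST	2	0	7
c.131G>T	p.Cys44Phe	MISSENSE	PATHOGENIC	BREAST	2	0	1
c.181T>G	p.Cys61Gly	MISSENSE	PATHOGENIC	BREAST	5	0	6
c.962G>A	p.Trp321Ter	NONSENSE	PATHOGENIC	BREAST	0	1	1
dupEx3-8	p.Gly183Valfs*4	FRAMESHIFT	PATHOGENIC	BREAST	1	0	1
c.5095C>T	p.Arg1699Trp	MISSENSE	PATHOGENIC	BREAST	1	0	2
c.5123C>A	p.Ala1708Glu	MISSENSE	PATHOGENIC	BREAST	0	1	0
c.5266dup	p.Gln1756Profs*74	FRAMESHIFT	PATHOGENIC	BREAST	3	1	13
c.5324T>G	p.Met1775Arg	MISSENSE	PATHOGENIC	BREAST	1	0	1
c.5453A>G	p.(Gly1803Glnfs*11)	FRAMESHIFT	PATHOGENIC	BREAST	1	0	0
c.1067A>G	p.Gln356Arg	MISSENSE	BENIGN	BREAST	4	2	1
c.2477C>A	p.Thr826Lys	MISSENSE	BENIGN	BREAST	1	1	0
c.4535G>T	p.Ser1512Ile	MISSENSE	BENIGN	BREAST	2	1	2
c.4812A>G	p.Gln1604Gln	SYNONYMOUS	LIKELY_BENIGN	BREAST	2	0	1
c.4955T>C	p.Met1652Thr	MISSENSE	LIKELY_BENIGN	BREAST	1	0	0
c.4956G>A	p.Met1652Thr	MISSENSE	BENIGN	BREAST	5	0	0
c.5117G>C	p.Gly1706Ala	MISSENSE	BENIGN	BREAST	1	0	1
c.5531T>C	p.Leu1844Pro	MISSENSE	BENIGN	BREAST	1	0	0
c.181T>G	p.Cys61Gly	MISSENSE	PATHOGENIC	OVARY	0	0	1
c.2477C>A	p.Thr826Lys	MISSENSE	BENIGN	OVARY	0	0	1
dupEx3-8	p.Gly183Valfs*4	FRAMESHIFT	PATHOGENIC	OVARY	0	0	1
c.5266dup	p.Gln1756Profs*74	FRAMESHIFT	PATHOGENIC	OVARY	0	0	1
c.5324T>G	p.Met1775Arg	MISSENSE	PATHOGENIC	OVARY	0	0	1
c.3074C>T	p.Thr1025Ile	MISSENSE	VUS	BREAST	1	0	0
c.4841C>T	p.Pro1614Leu	MISSENSE	VUS	BREAST	0	1	1
c.4963T>C	p.Ser1655Pro	MISSENSE	VUS	BREAST	1	0	3
c.4963T>C	p.Ser1655Pro	MISSENSE	VUS	OVARY	0	0	1
c.5057A>G	p.His1686Arg	MISSENSE	VUS	BREAST	0	0	1
c.5072C>A	p.Thr1691Lys	MISSENSE	VUS	BREAST	1	0	0
c.5177G>T	p.Arg1726Ile	MISSENSE	VUS	BREAST	1	0	0
c.5203G>A	p.Glu1735Lys	MISSENSE	VUS	BREAST	0	0	1
c.5497G>A	p.Val1833Met	MISSENSE	VUS	BREAST	0	0	2
c.5497G>A	p.Val1833Met	MISSENSE	VUS	OVARY	0	0	1
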