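# Multifactorial classification inputs for the two BRCT-domain variants
# that reached a causality score in the reference study. Component
# likelihood ratios (co-segregation, tumor pathology, family history)
# are consumed as inputs; the prior is 0.03 for both.
# reported_* columns are the published odds/posterior for cross-reference.
# NOTE: the published c.5497G>A row is internally inconsistent (its odds,
# 442.75, matches neither the product of its LRs nor its posterior); it is
# carried for completeness but excluded from numeric checks.
variant_id	hgvs_p	prior	lr_cosegregation	lr_pathology	lr_family_history	reported_odds	reported_posterior
c.4963T>C	p.Ser1655Pro	0.03	68.44	152.88	8.71	91176.32	0.99965
c.5497G>A	p.Val1833Met	0.03	7.85	480.48	272.76	442.75	0.99865
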