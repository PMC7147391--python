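# Synthetic default instrument weights for the three DMA% SNPs (v1).
# These are NOT transcribed published values: the per-allele effects were
# calibrated so that the weighted score reproduces the published cohort
# score distribution (median GP-DMA% 17.4 relative to a zero-carrier
# baseline; quartile steps 1.4 and 2.9 percentage points) and the stated
# qualitative facts (rs9527 and rs61735836 have large effects relative to
# rs11191527, and low-efficiency alleles are rare at rs9527/rs61735836).
# Effect alleles are the high-efficiency alleles; letters are placeholders.
# Units: beta_dma in DMA percentage points per effect-allele copy.
snp_id	effect_allele	beta_dma	se
rs9527	G	2.9	0.60
rs11191527	C	1.4	0.50
rs61735836	A	4.4	0.80
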