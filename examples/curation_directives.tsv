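gene	action	targets	merged_label	reason
CYP2C19	drop_allele	*35		unknown clinical function
CYP2C19	drop_variant_from_allele	*2,10:96541615:C:T		proxy variant in complete LD (r2=1.0) with rs4244285; one variant suffices
DPYD	merge_alleles	*9A,*9B	*9	unnecessary proxy suballeles collapsed
SLCO1B1	drop_allele	*15,*16,*17		unknown-function alleles removed (synthetic stand-ins for the full list)
CYP2D6	drop_allele	*2A,*2B,*4A		unnecessary suballeles (synthetic stand-ins)
CYP2D6	drop_structural_for_platform			deletion/duplication alleles undetectable without CNV support
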