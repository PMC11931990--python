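# Molar extinction coefficients (M^-1 cm^-1) used for concentration and
# incorporation-ratio estimates, plus the bound-Atto-495 absorbance
# correction factor (dimensionless).
name,value,units
agp1_apo_280nm,100000,M-1cm-1
agp1_pcm_apo_280nm,78400,M-1cm-1
agp1_pr_700nm,90000,M-1cm-1
agp2_apo_280nm,81300,M-1cm-1
agp2_pcm_apo_280nm,57900,M-1cm-1
agp2_hk_rr_280nm,23600,M-1cm-1
agp2_pfr_750nm,45000,M-1cm-1
free_bv_696nm_meoh_hcl,30800,M-1cm-1
atto495_495nm,80000,M-1cm-1
atto565_565nm,120000,M-1cm-1
bound_atto495_correction,0.7,dimensionless
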