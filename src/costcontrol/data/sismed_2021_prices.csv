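arm_id,drug_label,pack_mg,pens_per_pack,monthly_base,monthly_min,monthly_max
sema,Semaglutide 1.0 mg once-weekly,4,1,486946.24,479403.52,503170.95
dula,Dulaglutide 1.5 mg once-weekly,6,4,489762.03,484818.30,490314.51
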