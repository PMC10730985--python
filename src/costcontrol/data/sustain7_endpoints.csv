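endpoint_id,label,kind,arm_id,proportion_pct,n
hba1c_lt7,HbA1c <7.0%,glycemic,sema,79,299
hba1c_lt7,HbA1c <7.0%,glycemic,dula,67,299
hba1c_le6_5,HbA1c <=6.5%,glycemic,sema,67,299
hba1c_le6_5,HbA1c <=6.5%,glycemic,dula,47,299
hba1c_lt7_no_hypo_no_gain,"HbA1c <7.0% without hypoglycemia, and no weight gain",composite,sema,74,299
hba1c_lt7_no_hypo_no_gain,"HbA1c <7.0% without hypoglycemia, and no weight gain",composite,dula,58,299
wl_ge5,Weight loss >=5%,weight,sema,63,299
wl_ge5,Weight loss >=5%,weight,dula,30,299
wl_ge10,Weight loss >=10%,weight,sema,27,299
wl_ge10,Weight loss >=10%,weight,dula,8,299
hba1c_red1_wl3,">=1.0% HbA1c reduction and >=3.0% weight loss",composite,sema,68,299
hba1c_red1_wl3,">=1.0% HbA1c reduction and >=3.0% weight loss",composite,dula,35,299
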