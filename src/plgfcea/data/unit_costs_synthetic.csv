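item,unit,cost_gbp,activity
outpatient,attendance,120,
antenatal_ward,bed_day,450,
labour_ward,bed_day,750,
maternal_postnatal,bed_day,400,
maternal_icu_hdu,bed_day,1200,
infant_icu_hdu,bed_day,1000,
infant_scbu,bed_day,1000,
delivery_spontaneous,delivery,1985,
delivery_assisted,delivery,2653,
delivery_planned_CS,delivery,3781,
delivery_emergency_CS,delivery,5074,
plgf_test,test,70,
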