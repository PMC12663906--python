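airbase,area_ha,survey_start,survey_end,n_strikes,pct_species_known,n_count_surveys,n_inspections
De Kooy,118.6,2005,2022,57,64.9,1714,22637
Leeuwarden,424.2,1995,2022,285,91.2,4528,28088
Volkel,486.5,1995,2022,221,85.5,3577,31366
Eindhoven,526.9,1995,2022,957,94.4,4153,52985
Gilze-Rijen,670.7,1995,2022,65,81.5,3402,21653
Woensdrecht,220.3,1995,2022,78,83.3,3981,24758
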