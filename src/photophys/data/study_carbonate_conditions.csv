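light,target_pco2,temp_c,salinity,ph_nbs,dic_umol_kg,po4_umol_l,si_umol_l,ref_ta_umol_kg,ref_pco2_ppm,ref_co3_umol_kg,ref_hco3_umol_kg,ref_co2_umol_kg
31,390,18,35,8.14,1976,21,52.5,2302,312,215,1750,10.7
31,750,18,35,7.92,2007,21,52.5,2213,551,138,1850,18.9
81,390,18,35,8.18,1866,21,52.5,2212,300,209,1632,9.1
81,750,18,35,7.85,2047,21,52.5,2226,656,121,1903,22.5
167,390,18,35,8.10,1902,21,52.5,2196,332,191,1700,11.4
167,750,18,35,7.82,2024,21,52.5,2186,706,111,1889,24.2
242,390,18,35,8.10,1908,21,52.5,2110,321,184,1630,11.0
242,750,18,35,7.86,2064,21,52.5,2282,639,126,1916,22.0
380,390,18,35,8.16,1947,21,52.5,2286,295,223,1714,10.1
380,750,18,35,7.82,2152,21,52.5,2320,745,119,2007,25.5
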