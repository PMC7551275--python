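sex,age_min,age_max,gfr_min,gfr_max,median_umol_per_kg_day
male,18,40,0,15,180
male,18,40,15,30,195
male,18,40,30,45,210
male,18,40,45,60,220
male,18,40,60,1000,230
male,40,60,0,15,160
male,40,60,15,30,180
male,40,60,30,45,195
male,40,60,45,60,205
male,40,60,60,1000,215
male,60,80,0,15,140
male,60,80,15,30,160
male,60,80,30,45,180
male,60,80,45,60,190
male,60,80,60,1000,200
male,80,110,0,15,115
male,80,110,15,30,130
male,80,110,30,45,145
male,80,110,45,60,155
male,80,110,60,1000,165
female,18,40,0,15,140
female,18,40,15,30,152
female,18,40,30,45,164
female,18,40,45,60,172
female,18,40,60,1000,179
female,40,60,0,15,125
female,40,60,15,30,140
female,40,60,30,45,152
female,40,60,45,60,160
female,40,60,60,1000,168
female,60,80,0,15,109
female,60,80,15,30,125
female,60,80,30,45,140
female,60,80,45,60,148
female,60,80,60,1000,156
female,80,110,0,15,90
female,80,110,15,30,101
female,80,110,30,45,113
female,80,110,45,60,121
female,80,110,60,1000,129
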