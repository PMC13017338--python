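variable,rest,at,peak,pred,pct_of_pred
vo2_rel_ml_kg_min,4,22.6,26.8,25.8,104
vo2_l_min,0.53,3,3.56,3.42,104
vco2_l_min,0.42,2.94,3.61,4.14,87
speed_mph,,3,3,,
grade_pct,,8,9,,
mets,1.2,6.5,7.7,7.4,104
hr_bpm,92,161,174,183,95
sys_bp_mmhg,,184,190,,
dia_bp_mmhg,,67,77,,
hrr_bpm,91,22,9,,
o2_pulse_ml_beat,6,19,21,19,110
ve_btps_l_min,12.9,84.4,112.5,138,82
br_pct,90.7,39,18.7,,
vt_btps_l,0.9,2.78,2.63,,
rr_br_min,14,30,43,,
ve_mvv_pct,9,61,81,,
petco2_mmhg,38,39,37,,
peto2_mmhg,98,103,108,,
ve_vco2,31,29,31,23,133
ve_vo2,24,28,32,28,112
vd_vt_est,0.2,0.13,0.14,,
rer,0.79,0.98,1.02,,
spo2_pct,97,98,99,,
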