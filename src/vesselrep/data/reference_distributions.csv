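weighting,metric,sequence,median,iqr
T1W,muscle_snr,gated,19.3,8.9
T1W,muscle_snr,ungated,15.2,7.8
T1W,wall_snr,gated,11.2,4.0
T1W,wall_snr,ungated,9.0,4.3
T1W,lumen_snr,gated,3.2,1.1
T1W,lumen_snr,ungated,3.0,0.7
T1W,wall_cnr,gated,7.6,3.6
T1W,wall_cnr,ungated,6.6,3.8
T1W,wall_cnreff,gated,6.6,3.2
T1W,wall_cnreff,ungated,6.4,3.7
T1W,lumen_area,gated,0.446,0.145
T1W,lumen_area,ungated,0.452,0.112
T1W,wall_area,gated,0.277,0.279
T1W,wall_area,ungated,0.293,0.132
T2W,muscle_snr,gated,12.8,8.7
T2W,muscle_snr,ungated,6.6,2.6
T2W,wall_snr,gated,10.0,4.9
T2W,wall_snr,ungated,6.7,3.1
T2W,lumen_snr,gated,3.7,1.6
T2W,lumen_snr,ungated,2.7,0.4
T2W,wall_cnr,gated,7.3,4.9
T2W,wall_cnr,ungated,4.3,3.0
T2W,wall_cnreff,gated,4.9,3.3
T2W,wall_cnreff,ungated,5.2,3.6
T2W,lumen_area,gated,0.410,0.141
T2W,lumen_area,ungated,0.385,0.295
T2W,wall_area,gated,0.272,0.283
T2W,wall_area,ungated,0.337,0.129
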