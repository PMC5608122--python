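weighting,metric,sequence,bias,loa_range
T1W,muscle_snr,gated,0.11,11.5
T1W,muscle_snr,ungated,0.58,3.5
T1W,wall_snr,gated,0.06,5.5
T1W,wall_snr,ungated,0.29,2.08
T1W,wall_cnr,gated,-0.10,4.5
T1W,wall_cnr,ungated,0.15,2.4
T1W,lumen_area,gated,0.03,0.13
T1W,lumen_area,ungated,-0.01,0.07
T1W,wall_area,gated,-0.01,0.11
T1W,wall_area,ungated,0.01,0.10
T2W,muscle_snr,gated,0.11,6.7
T2W,muscle_snr,ungated,-0.03,0.5
T2W,wall_snr,gated,-0.04,3.0
T2W,wall_snr,ungated,0.11,1.5
T2W,wall_cnr,gated,0.18,3.1
T2W,wall_cnr,ungated,0.11,1.5
T2W,lumen_area,gated,0.02,0.11
T2W,lumen_area,ungated,0.02,0.08
T2W,wall_area,gated,0.01,0.15
T2W,wall_area,ungated,-0.01,0.08
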