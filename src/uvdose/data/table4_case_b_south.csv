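beta_deg,ierdh,ierbh,idag,idas,cos_incidence,iba,ia,ua_j_m2,sed
0.0,0.158,0.056,0.0,0.158,0.938,0.056,0.214,770,7.7
15.0,0.158,0.056,4.01e-05,0.164,0.996,0.059,0.223,803,8.0
30.0,0.158,0.056,0.000158,0.167,0.986,0.059,0.226,814,8.1
45.0,0.158,0.056,0.000345,0.169,0.908,0.054,0.223,803,8.0
60.0,0.158,0.056,0.000589,0.168,0.769,0.046,0.214,770,7.7
75.0,0.158,0.056,0.000872,0.164,0.577,0.035,0.2,720,7.2
90.0,0.158,0.056,0.00118,0.159,0.346,0.021,0.181,652,6.5
23.4,0.158,0.056,9.72e-05,0.166,1.0,0.06,0.226,814,8.1
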