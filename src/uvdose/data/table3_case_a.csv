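direction,gamma_deg,ierdh,ierbh,idag,idas,cos_incidence,iba,ia,ua_j_m2,sed
south,0.0,0.158,0.056,0.001,0.159,0.346,0.021,0.181,652.0,6.5
west,90.0,0.158,0.056,0.001,0.159,0.0,0.0,0.16,576.0,5.8
east,-90.0,0.158,0.056,0.001,0.159,0.0,0.0,0.16,576.0,5.8
north,180.0,0.158,0.056,0.001,0.159,-0.346,0.0,0.16,576.0,5.8
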