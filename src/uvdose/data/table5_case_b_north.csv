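beta_deg,ierdh,ierbh,idag,idas,cos_incidence,iba,ia,ua_j_m2,sed
15,0.158,0.056,0.00231,0.116,-0.996,0.0,0.119,428,4.3
30,0.158,0.056,0.0022,0.125,-0.986,0.0,0.127,457,4.6
45,0.158,0.056,0.00201,0.134,-0.908,0.0,0.136,490,4.9
60,0.158,0.056,0.00177,0.143,-0.769,0.0,0.145,522,5.2
75,0.158,0.056,0.00148,0.152,-0.577,0.0,0.153,551,5.5
90,0.158,0.056,0.00102,0.159,-0.346,0.0,0.16,576,5.8
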