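phototype,sensitivity,cutaneous_response,cancer_risk,med_j_m2
I,Extremely sensitive,Always burns,++++,150
II,Very sensitive,Burns easily,+++/++++,250
III,Sensitive,Burns moderately,+++,300
IV,Mildly sensitive,Burns minimally,++,400
V,Resistant skin,Rarely burns,+,600
VI,Very resistant,Almost never burns,+/-,900
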