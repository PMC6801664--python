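site,latitude_deg,longitude_deg,altitude_m
rome,41.89,12.49,21.0
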