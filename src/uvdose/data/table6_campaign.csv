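site,date,day_of_year,latitude_deg,longitude_deg,altitude_m,toc_du,albedo_uv,utc_offset_h
rome,2019-02-21,52,41.54,12.28,21.0,345.0,0.057,2.0
guadagnolo,2019-02-25,56,41.91,12.92,1218.0,320.0,0.018,2.0
pisa,2019-05-16,136,43.72,10.39,4.0,363.0,0.055,2.0
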