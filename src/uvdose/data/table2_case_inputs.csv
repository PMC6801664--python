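key,value,note
toc_du,329.0,total ozone column
ierh_w_m2,0.214,erythemal horizontal irradiance (TUV estimate)
declination_deg,23.45,"printed solar declination, 21 June"
hour_angle_deg,0.0,printed hour angle (solar noon)
zenith_deg,20.27,printed solar zenith angle
albedo_uv,0.011,UV ground albedo (green grass)
eh_w_m2,931.6,total (broadband) horizontal irradiance
dt_exp_s,3600.0,exposure duration
day_of_year,172.0,21 June
latitude_deg,43.72,Pisa
longitude_deg,10.39,Pisa
altitude_m,4.0,Pisa
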