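site,time,beta_deg,gamma_deg,ua_j_m2
rome,11:30,90,0,12.96
rome,11:45,90,90,17.4
rome,12:00,90,-90,15.31
rome,12:15,0,,30.93
rome,12:30,45,0,38.02
rome,12:45,45,90,34.82
rome,13:00,45,-90,22.61
guadagnolo,13:00,90,180,11.59
guadagnolo,13:00,90,90,19.21
guadagnolo,13:00,90,0,36.42
guadagnolo,13:00,90,-90,11.51
guadagnolo,13:00,60,180,22.71
guadagnolo,13:00,60,0,48.11
guadagnolo,13:00,30,0,62.27
guadagnolo,13:00,0,,46.58
guadagnolo,13:15,90,180,11.1
guadagnolo,13:15,90,90,19.21
guadagnolo,13:15,90,0,33.77
guadagnolo,13:15,90,-90,10.91
guadagnolo,13:15,60,180,22.75
guadagnolo,13:15,60,0,44.7
guadagnolo,13:15,30,0,58.9
guadagnolo,13:15,0,,43.88
guadagnolo,13:30,90,180,10.66
guadagnolo,13:30,90,90,19.37
guadagnolo,13:30,90,0,32.57
guadagnolo,13:30,90,-90,10.3
guadagnolo,13:30,60,180,22.2
guadagnolo,13:30,60,0,42.79
guadagnolo,13:30,30,0,57.22
guadagnolo,13:30,0,,42.96
pisa,11:30,90,180,12.18
pisa,11:30,90,90,11.82
pisa,11:30,90,0,20.58
pisa,11:30,90,-90,23.82
pisa,11:30,45,180,29.76
pisa,11:30,45,0,84.12
pisa,11:30,0,,77.82
pisa,11:45,90,180,12.42
pisa,11:45,90,90,12.06
pisa,11:45,90,0,21.0
pisa,11:45,90,-90,20.76
pisa,11:45,45,180,31.68
pisa,11:45,45,0,98.28
pisa,11:45,0,,91.14
pisa,12:00,90,180,12.9
pisa,12:00,90,90,12.96
pisa,12:00,90,0,22.02
pisa,12:00,90,-90,20.94
pisa,12:00,45,180,34.08
pisa,12:00,45,0,96.54
pisa,12:00,0,,98.1
pisa,12:15,90,180,13.38
pisa,12:15,90,90,13.32
pisa,12:15,90,0,22.98
pisa,12:15,90,-90,18.72
pisa,12:15,45,180,33.36
pisa,12:15,45,0,99.78
pisa,12:15,0,,102.18
pisa,12:30,90,180,14.1
pisa,12:30,90,90,14.34
pisa,12:30,90,0,24.96
pisa,12:30,90,-90,18.12
pisa,12:30,45,180,36.3
pisa,12:30,45,0,106.98
pisa,12:30,0,,111.12
pisa,12:45,90,180,13.68
pisa,12:45,90,90,14.4
pisa,12:45,90,0,25.98
pisa,12:45,90,-90,17.76
pisa,12:45,45,180,37.74
pisa,12:45,45,0,110.52
pisa,12:45,0,,115.08
pisa,13:00,90,180,14.82
pisa,13:00,90,90,15.66
pisa,13:00,90,0,26.58
pisa,13:00,90,-90,17.04
pisa,13:00,45,180,35.1
pisa,13:00,45,0,116.7
pisa,13:00,0,,114.54
pisa,13:15,90,180,14.22
pisa,13:15,90,90,15.72
pisa,13:15,90,0,25.74
pisa,13:15,90,-90,14.88
pisa,13:15,45,180,36.78
pisa,13:15,45,0,109.56
pisa,13:15,0,,118.68
pisa,13:30,90,180,15.78
pisa,13:30,90,90,16.98
pisa,13:30,90,0,25.92
pisa,13:30,90,-90,15.18
pisa,13:30,45,180,38.28
pisa,13:30,45,0,115.26
pisa,13:30,0,,106.02
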