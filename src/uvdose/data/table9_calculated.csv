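site,time,beta_deg,gamma_deg,ua_j_m2
rome,11:30,90,0,18.85
rome,11:45,90,90,15.57
rome,12:00,90,-90,15.99
rome,12:15,0,,31.8
rome,12:30,45,0,28.96
rome,12:45,45,90,26.22
rome,13:00,45,-90,25.2
guadagnolo,13:00,90,180,22.39
guadagnolo,13:00,90,90,25.15
guadagnolo,13:00,90,0,35.43
guadagnolo,13:00,90,-90,22.99
guadagnolo,13:00,60,180,33.89
guadagnolo,13:00,60,0,49.48
guadagnolo,13:00,30,0,56.28
guadagnolo,13:00,0,,54.0
guadagnolo,13:15,90,180,20.86
guadagnolo,13:15,90,90,24.46
guadagnolo,13:15,90,0,34.54
guadagnolo,13:15,90,-90,14.86
guadagnolo,13:15,60,180,30.79
guadagnolo,13:15,60,0,48.07
guadagnolo,13:15,30,0,54.32
guadagnolo,13:15,0,,51.6
guadagnolo,13:30,90,180,20.44
guadagnolo,13:30,90,90,23.61
guadagnolo,13:30,90,0,30.51
guadagnolo,13:30,90,-90,20.44
guadagnolo,13:30,60,180,30.22
guadagnolo,13:30,60,0,42.94
guadagnolo,13:30,30,0,49.34
guadagnolo,13:30,0,,48.0
pisa,11:30,90,180,14.62
pisa,11:30,90,90,14.62
pisa,11:30,90,0,21.04
pisa,11:30,90,-90,26.14
pisa,11:30,45,180,32.48
pisa,11:30,45,0,82.41
pisa,11:30,0,,85.05
pisa,11:45,90,180,11.52
pisa,11:45,90,90,11.52
pisa,11:45,90,0,22.37
pisa,11:45,90,-90,24.43
pisa,11:45,45,180,31.5
pisa,11:45,45,0,88.98
pisa,11:45,0,,89.97
pisa,12:00,90,180,11.42
pisa,12:00,90,90,11.42
pisa,12:00,90,0,23.79
pisa,12:00,90,-90,22.23
pisa,12:00,45,180,32.26
pisa,12:00,45,0,94.02
pisa,12:00,0,,94.34
pisa,12:15,90,180,11.27
pisa,12:15,90,90,11.28
pisa,12:15,90,0,24.98
pisa,12:15,90,-90,21.74
pisa,12:15,45,180,32.82
pisa,12:15,45,0,98.24
pisa,12:15,0,,97.95
pisa,12:30,90,180,11.11
pisa,12:30,90,90,11.15
pisa,12:30,90,0,25.96
pisa,12:30,90,-90,18.39
pisa,12:30,45,180,33.24
pisa,12:30,45,0,101.7
pisa,12:30,0,,100.89
pisa,12:45,90,180,10.97
pisa,12:45,90,90,11.02
pisa,12:45,90,0,26.67
pisa,12:45,90,-90,14.73
pisa,12:45,45,180,43.11
pisa,12:45,45,0,104.23
pisa,12:45,0,,103.02
pisa,13:00,90,180,10.92
pisa,13:00,90,90,10.98
pisa,13:00,90,0,27.11
pisa,13:00,90,-90,10.89
pisa,13:00,45,180,33.72
pisa,13:00,45,0,105.76
pisa,13:00,0,,104.33
pisa,13:15,90,180,11.51
pisa,13:15,90,90,11.7
pisa,13:15,90,0,27.28
pisa,13:15,90,-90,7.48
pisa,13:15,45,180,43.96
pisa,13:15,45,0,106.05
pisa,13:15,0,,104.76
pisa,13:30,90,180,14.99
pisa,13:30,90,90,19.86
pisa,13:30,90,0,27.33
pisa,13:30,90,-90,10.83
pisa,13:30,45,180,37.52
pisa,13:30,45,0,103.68
pisa,13:30,0,,104.31
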