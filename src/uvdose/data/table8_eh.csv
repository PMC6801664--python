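site,time,eh_w_m2
rome,11:30,160.99
rome,11:45,159.6
rome,12:00,157.04
rome,12:15,153.27
rome,12:30,148.57
rome,12:45,142.96
rome,13:00,136.48
guadagnolo,13:00,100.08
guadagnolo,13:15,102.12
guadagnolo,13:30,103.77
pisa,11:30,851.92
pisa,11:45,874.68
pisa,12:00,894.84
pisa,12:15,911.96
pisa,12:30,925.72
pisa,12:45,935.56
pisa,13:00,940.2
pisa,13:15,922.2
pisa,13:30,911.88
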