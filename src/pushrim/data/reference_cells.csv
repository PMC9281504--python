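parameter,condition,side,mean,sd
po_peak,with_racket,dominant,112.53,63.74
po_peak,with_racket,non_dominant,105.00,51.43
po_peak,without_racket,dominant,104.78,65.87
po_peak,without_racket,non_dominant,95.98,55.43
mz_peak,with_racket,dominant,22.24,8.21
mz_peak,with_racket,non_dominant,21.61,8.76
mz_peak,without_racket,dominant,20.55,10.53
mz_peak,without_racket,non_dominant,19.56,10.22
ftot_peak,with_racket,dominant,117.77,45.36
ftot_peak,with_racket,non_dominant,86.53,40.75
ftot_peak,without_racket,dominant,86.53,38.65
ftot_peak,without_racket,non_dominant,73.75,38.81
fef,with_racket,dominant,29.36,6.93
fef,with_racket,non_dominant,40.85,14.15
fef,without_racket,dominant,35.82,10.94
fef,without_racket,non_dominant,41.14,13.14
ror,with_racket,dominant,587.42,305.96
ror,with_racket,non_dominant,388.64,228.52
ror,without_racket,dominant,388.65,210.90
ror,without_racket,non_dominant,289.02,181.49
ai,with_racket,dominant,4.01,2.00
ai,with_racket,non_dominant,4.00,2.19
ai,without_racket,dominant,4.25,2.41
ai,without_racket,non_dominant,4.10,2.44
pt,with_racket,dominant,0.34,0.10
pt,with_racket,non_dominant,0.34,0.08
pt,without_racket,dominant,0.36,0.07
pt,without_racket,non_dominant,0.37,0.07
ct,with_racket,dominant,1.13,0.43
ct,with_racket,non_dominant,1.11,0.39
ct,without_racket,dominant,1.29,0.45
ct,without_racket,non_dominant,1.30,0.45
pa,with_racket,dominant,84.68,30.47
pa,with_racket,non_dominant,83.22,19.44
pa,without_racket,dominant,90.98,19.60
pa,without_racket,non_dominant,91.06,19.23
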