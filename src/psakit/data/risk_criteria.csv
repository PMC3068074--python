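group,t_stages,psa_min,psa_max,gleason_min,gleason_max,failure_lo,failure_hi,surv5,surv10
low,T1c|T2a,,10,,6,,25,85,83
intermediate,T2b,,,,,25,50,60,46
intermediate,,,,7,7,25,50,60,46
intermediate,,10,20,,,25,50,60,46
high,T2c,,,,,50,,30,29
high,,20,,,,50,,30,29
high,,,,8,,50,,30,29
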