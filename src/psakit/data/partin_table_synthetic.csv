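t_category,psa_min,psa_max,gleason_min,gleason_max,organ_confined_pct,extraprostatic_extension_pct,seminal_vesicle_invasion_pct,lymph_node_involvement_pct
T1c,0,4,2,6,84.7,11.5,2.8,1.0
T1c,0,4,7,7,63.0,26.2,7.7,3.1
T1c,0,4,8,10,37.1,42.0,14.6,6.3
T1c,4,10,2,6,74.1,18.8,5.1,2.0
T1c,4,10,7,7,46.7,36.4,11.9,5.0
T1c,4,10,8,10,23.3,49.2,18.9,8.6
T1c,10,20,2,6,56.6,30.3,9.3,3.8
T1c,10,20,7,7,28.4,46.7,17.2,7.7
T1c,10,20,8,10,12.0,53.6,23.1,11.3
T1c,20,,2,6,34.1,43.7,15.4,6.8
T1c,20,,7,7,13.5,53.2,22.5,10.8
T1c,20,,8,10,5.0,54.1,26.9,14.0
T2a,0,4,2,6,74.1,18.8,5.1,2.0
T2a,0,4,7,7,46.7,36.4,11.9,5.0
T2a,0,4,8,10,23.3,49.2,18.9,8.6
T2a,4,10,2,6,59.8,28.2,8.5,3.5
T2a,4,10,7,7,31.1,45.3,16.3,7.3
T2a,4,10,8,10,13.5,53.2,22.5,10.8
T2a,10,20,2,6,40.2,40.2,13.7,5.9
T2a,10,20,7,7,16.9,52.0,21.1,10.0
T2a,10,20,8,10,6.5,54.3,25.9,13.3
T2a,20,,2,6,21.0,50.3,19.6,9.1
T2a,20,,7,7,7.4,54.3,25.4,12.9
T2a,20,,8,10,2.6,52.6,28.9,15.9
T2b,0,4,2,6,59.8,28.2,8.5,3.5
T2b,0,4,7,7,31.1,45.3,16.3,7.3
T2b,0,4,8,10,13.5,53.2,22.5,10.8
T2b,4,10,2,6,43.4,38.3,12.8,5.5
T2b,4,10,7,7,18.9,51.2,20.4,9.5
T2b,4,10,8,10,7.4,54.3,25.4,12.9
T2b,10,20,2,6,25.7,48.1,18.0,8.2
T2b,10,20,7,7,9.4,54.2,24.3,12.1
T2b,10,20,8,10,3.5,53.3,28.1,15.1
T2b,20,,2,6,12.0,53.6,23.1,11.3
T2b,20,,7,7,3.9,53.6,27.7,14.8
T2b,20,,8,10,1.4,50.4,30.6,17.6
T2c,0,4,2,6,43.4,38.3,12.8,5.5
T2c,0,4,7,7,18.9,51.2,20.4,9.5
T2c,0,4,8,10,7.4,54.3,25.4,12.9
T2c,4,10,2,6,28.4,46.7,17.2,7.7
T2c,4,10,7,7,10.6,53.9,23.8,11.7
T2c,4,10,8,10,3.9,53.6,27.7,14.8
T2c,10,20,2,6,15.1,52.7,21.8,10.4
T2c,10,20,7,7,5.0,54.1,26.9,14.0
T2c,10,20,8,10,1.8,51.4,29.9,16.9
T2c,20,,2,6,6.5,54.3,25.9,13.3
T2c,20,,7,7,2.0,51.8,29.6,16.6
T2c,20,,8,10,0.7,47.8,32.1,19.4
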