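nins_vf,nccf_vf,status,gauge_factor,critical_strain
3,0.5,NC,,
5,0.5,NC,,
6,0.5,NC,,
7,0.5,NC,,
11,0.5,NC,,
3,0.75,NC,,
5,0.75,NC,,
6,0.75,C,8.56,0.23
7,0.75,C,9.35,0.23
11,0.75,MF,,
3,1.0,NC,,
5,1.0,NC,,
6,1.0,C,8.61,0.097
7,1.0,C,8.5,0.20
11,1.0,MF,,
3,1.5,NC,,
5,1.5,NC,,
6,1.5,C,3.79,0.036
7,1.5,C,7.63,0.037
11,1.5,MF,,
3,2.0,NC,,
5,2.0,C,5.49,0.12
6,2.0,C,4.55,0.054
7,2.0,C,3.08,0.049
11,2.0,C,13.5,0.006
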