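band,elementary,middle
<0.25,53.1,65.5
0.25-0.5,25.5,49.9
0.5-1,13.9,18.5
1-2,2.6,7.2
>=2,1.3,2.0
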