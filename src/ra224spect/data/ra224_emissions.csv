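nuclide,energy_keV,probability_pct,ray_type
Tl-208,73.0,0.8,x
Pb-212,75.1,10.6,x
Tl-208,75.3,1.4,x
Pb-212,77.4,17.7,x
Pb-212,87.1,2.0,x
Pb-212,87.7,3.8,x
Pb-212,90.2,0.9,x
Pb-212,115,0.6,gamma
Pb-212,239,43.3,gamma
Ra-224,241,4.1,gamma
Tl-208,277,2.3,gamma
Pb-212,300,3.3,gamma
Tl-208,511,8.1,gamma
Tl-208,583,30.3,gamma
Bi-212,727,4.2,gamma
Tl-208,763,0.7,gamma
Bi-212,785,0.7,gamma
Tl-208,861,4.5,gamma
Bi-212,1621,1.0,gamma
Tl-208,2615,35.6,gamma
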