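group,r_test_lung,r_humid,pressure_hpa,temp_c,rh_pct,r_dry
a,1.00118,0.98289,1002,22.7,91.7,1.00834
a,1.00118,0.98098,1002,22.8,91.6,1.00653
a,0.99903,0.97958,1007,23.3,91.5,1.00571
a,0.99903,0.98047,1003,23.4,90.7,1.00666
a,0.99643,0.98316,1020,23.1,91.8,1.00882
a,1.00195,0.98181,1012,23.3,89.9,1.00742
b,1.00118,0.97981,1002,22.5,92.5,1.00510
b,1.00118,0.98382,1002,22.8,91.6,1.00944
b,0.99903,0.97780,1007,23.5,90.7,1.00397
b,0.99903,0.98420,1003,23.0,90.9,1.00990
b,0.99643,0.98330,1020,22.8,91.8,1.00849
b,1.00195,0.98302,1012,23.2,90.9,1.00879
c,1.00120,0.98360,993,22.9,92.2,1.01045
c,1.00465,0.98146,1027,22.7,90.3,1.00586
c,0.99995,0.98297,1023,22.6,90.4,1.00784
c,1.00127,0.98366,1010,22.4,89.5,1.00923
c,1.00249,0.98329,1013,23.1,92.3,1.00896
c,1.00195,0.98526,1013,23.2,91.4,1.01121
d,1.00120,0.98813,993,22.7,92.9,1.01465
d,1.00465,0.98288,1027,22.8,91.6,1.00768
d,0.99995,0.98532,1023,23.3,91.1,1.00999
d,1.00127,0.98338,1010,23.4,91.7,1.00817
d,1.00249,0.98546,1013,23.1,90.8,1.01107
d,1.00195,0.98723,1013,23.3,91.3,1.01320
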