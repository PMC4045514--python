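gp_ba,correction_boys,correction_girls
2.0,0.0,-0.2
2.5,-0.1,-0.2
3.0,-0.2,0.1
3.5,-0.2,0.3
4.0,-0.1,0.4
4.5,-0.0,0.4
5.0,0.0,0.3
5.5,0.1,0.1
6.0,0.2,-0.1
6.5,0.3,-0.1
7.0,0.5,0.2
7.5,0.6,0.3
8.0,0.5,0.2
8.5,0.4,0.1
9.0,0.3,-0.0
9.5,0.2,-0.1
10.0,0.1,-0.1
10.5,0.0,-0.2
11.0,-0.1,-0.2
11.5,-0.2,-0.3
12.0,-0.4,-0.5
12.5,-0.5,-0.6
13.0,-0.4,-0.7
13.5,-0.4,-0.8
14.0,-0.4,-0.9
14.5,-0.5,-1.0
15.0,-0.7,-1.2
15.5,-0.9,-1.2
16.0,-1.0,-1.1
16.5,-1.1,-1.1
17.0_and_above,-1.2,-1.2
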