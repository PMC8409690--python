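week,prevalence_threshold,susceptible,infected,recovered,ppv,zeta,pti
1,0.0931,,0.0001,,0.0094,0.0095,3
2,0.0931,,0.0002,,0.0186,0.0188,3
3,0.0931,,0.0004,,0.0366,0.0370,3
4,0.0931,,0.0009,,0.0788,0.0796,3
5,0.0931,,0.0020,,0.1599,0.1615,2
6,0.0931,,0.0041,,0.2811,0.2839,2
7,0.0931,,0.0087,,0.4547,0.4591,2
8,0.0931,,0.0181,,0.6365,0.6427,2
9,0.0931,,0.0376,,0.7878,0.7954,2
10,0.0931,,0.0766,,0.8874,0.8960,2
11,0.0931,,0.1502,,0.9438,0.9529,1
12,0.0931,,0.2733,,0.9728,0.9822,1
13,0.0931,,0.4289,,0.9862,0.9957,1
14,0.0931,,0.5208,,0.9904,1.0000,1
15,0.0931,,0.4563,,0.9876,0.9972,1
16,0.0931,,0.3281,,0.9789,0.9884,1
17,0.0931,,0.2246,,0.9649,0.9743,1
18,0.0931,,0.1519,,0.9445,0.9536,1
19,0.0931,,0.1022,,0.9154,0.9242,1
20,0.0931,,0.0687,,0.8751,0.8836,2
21,0.0931,,0.0461,,0.8211,0.8291,2
22,0.0931,,0.0309,,0.7518,0.7591,2
23,0.0931,,0.0207,,0.6676,0.6740,2
24,0.0931,,0.0139,,0.5725,0.5780,2
25,0.0931,,0.0093,,0.4714,0.4760,2
26,0.0931,,0.0062,,0.3721,0.3757,2
27,0.0931,,0.0042,,0.2861,0.2888,2
28,0.0931,,0.0028,,0.2106,0.2126,2
29,0.0931,,0.0019,,0.1531,0.1546,2
30,0.0931,,0.0013,,0.1101,0.1111,2
31,0.0931,,0.0008,,0.0707,0.0714,3
32,0.0931,,0.0006,,0.0540,0.0545,3
33,0.0931,,0.0004,,0.0366,0.0370,3
34,0.0931,,0.0003,,0.0277,0.0280,3
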