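displacement_mm,S16162010,S16162210,S16162410,S16162610,S16162009,S16162008,S20102007,S18252010,S00162010,A16162010
0.5,0.32,0.25,0.21,0.18,0.33,0.42,0.61,0.63,0.24,0.28
1.0,0.66,0.51,0.41,0.35,0.68,0.85,1.24,1.28,0.49,0.57
1.5,0.99,0.77,0.63,0.54,1.02,1.28,1.87,1.92,0.72,0.85
2.0,1.33,1.04,0.85,0.73,1.35,1.72,2.48,2.55,0.95,1.16
2.5,1.64,1.28,1.07,0.92,1.67,2.15,3.08,3.19,1.21,1.46
3.0,1.96,1.53,1.29,1.10,2.01,2.58,3.67,3.82,1.45,1.75
3.5,2.27,1.78,1.51,1.26,2.35,3.03,4.30,4.46,1.69,2.03
4.0,2.57,2.00,1.72,1.42,2.65,3.44,4.92,5.09,1.91,2.30
4.5,2.87,2.22,1.90,1.58,2.94,3.83,5.53,5.72,2.13,2.56
5.0,3.18,2.43,2.05,1.78,3.22,4.22,6.13,6.35,2.37,2.79
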