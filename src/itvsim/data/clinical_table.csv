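patient,m_cm,ptv_gs_cc,r_fb,dsc_fb,r_fbaug,dsc_fbaug,r_aip,dsc_aip,r_mip,dsc_mip
1,1.32,23.9,0.94,0.860,1.00,0.916,0.85,0.820,0.90,0.835
2,0.3,24.5,1.11,0.835,0.99,0.942,0.91,0.878,0.92,0.909
3,1.11,24.2,0.83,0.769,0.95,0.906,0.82,0.769,0.90,0.815
4,0.7,27.6,1.20,0.754,1.02,0.915,0.94,0.826,1.11,0.782
5,1.6,24.8,0.79,0.470,1.00,0.848,0.75,0.745,0.78,0.776
6,1.4,23.0,0.91,0.614,0.95,0.848,0.91,0.795,0.86,0.768
7,0.8,61.8,1.12,0.785,1.03,0.874,0.90,0.791,0.97,0.872
8,0.9,21.4,1.19,0.643,1.12,0.809,0.77,0.745,0.94,0.853
9,2.2,63.4,0.66,0.538,0.92,0.894,0.80,0.784,0.95,0.853
10,0.9,109.6,1.07,0.842,1.00,0.928,0.89,0.866,0.91,0.872
11,0.5,23.1,0.82,0.770,0.90,0.888,0.69,0.913,0.71,0.690
12,1.1,51.5,1.18,0.734,1.08,0.874,0.92,0.755,0.91,0.848
13,1.3,29.8,1.34,0.690,1.19,0.784,0.77,0.790,1.10,0.861
14,0.2,52.6,1.45,0.671,1.28,0.774,1.22,0.788,1.31,0.735
15,1.0,40.1,1.24,0.803,1.00,0.995,1.04,0.783,1.03,0.813
16,0.1,18.3,1.33,0.721,1.08,0.886,1.03,0.869,1.10,0.855
17,0.9,33.4,1.02,0.732,1.00,0.892,0.77,0.743,0.74,0.731
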