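pdb_id,hybrid_homologous_AF_unpruned,hybrid_homologous_AF_pruned,hybrid_human_AF_unpruned,hybrid_human_AF_pruned,AF3_unpruned,AF3_pruned,AF2_unpruned,AF2_pruned
6D9H,2.594,0.879,2.615,0.871,2.630,0.938,2.594,0.879
7AUE,1.715,1.126,1.760,1.028,2.606,1.095,1.760,1.028
7F4D,1.698,1.121,1.403,0.922,1.841,1.034,1.403,0.922
7F53,1.145,0.949,1.767,0.919,1.741,0.777,1.766,0.914
7LD3,2.374,0.857,2.490,0.905,2.554,0.992,2.491,0.914
7PIU,2.357,0.960,1.538,0.929,2.263,0.804,1.537,0.903
7WKD,1.959,1.008,1.961,0.990,1.928,1.017,3.359,0.930
7X1T,2.078,1.061,2.080,1.060,2.057,1.021,2.081,1.057
8EFB,1.539,0.807,1.520,0.813,3.173,1.018,1.526,1.067
8F7Q,1.554,0.860,1.588,0.864,3.096,1.107,1.560,1.035
8F7W,2.715,1.105,2.725,1.118,3.168,1.109,2.727,0.858
8F7X,1.835,0.954,3.010,1.032,3.205,1.008,3.010,1.118
8HDO,3.428,1.016,3.333,1.006,3.279,0.959,3.340,1.033
8HTI,1.903,1.022,1.905,1.048,2.159,0.874,2.008,0.998
8ZPS,2.454,1.053,2.492,1.059,2.565,1.107,2.492,1.071
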