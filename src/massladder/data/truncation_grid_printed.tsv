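# Published C-terminal truncation / water-loss grid for the ovine 70mer.
# Columns: mer, lost_residues, M, MH+, then MH+ minus 1..8 waters.
# NOTE: the published MH+ cell of the 69mer row (8045.86) is not equal to its
# own M cell plus 1.008 (8044.84 + 1.008 = 8045.85); the row is internally
# inconsistent as printed.  Values below are transcribed verbatim.
70	-	8175.01	8176.02	8158.00	8139.99	8121.97	8103.96	8085.94	8067.93	8049.91	8031.90
69	-I	8044.84	8045.86	8027.84	8009.83	7991.81	7973.80	7955.78	7937.77	7919.75	7901.74
68	-NI	7930.74	7931.75	7913.73	7895.72	7877.70	7859.69	7841.67	7823.66	7805.64	7787.63
67	-NNI	7816.64	7817.65	7799.63	7781.62	7763.60	7745.59	7727.57	7709.56	7691.54	7673.53
66	-ANNI	7745.56	7746.57	7728.55	7710.54	7692.52	7674.51	7656.49	7638.48	7620.46	7602.45
65	-KANNI	7617.38	7618.39	7600.37	7582.36	7564.34	7546.33	7528.31	7510.30	7492.28	7474.27
64	-YKANNI	7454.21	7455.22	7437.20	7419.19	7401.17	7383.16	7365.14	7347.13	7329.11	7311.10
63	-IYKANNI	7341.05	7342.06	7324.04	7306.03	7288.01	7270.00	7251.98	7233.97	7215.95	7197.94
62	-DIYKANNI	7225.96	7226.97	7208.95	7190.94	7172.92	7154.91	7136.89	7118.88	7100.86	7082.85
61	-DDIYKANNI	7110.87	7111.88	7093.86	7075.85	7057.83	7039.82	7021.80	7003.79	6985.77	6967.76
60	-EDDIYKANNI	6981.76	6982.77	6964.75	6946.74	6928.72	6910.71	6892.69	6874.68	6856.66	6838.65
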