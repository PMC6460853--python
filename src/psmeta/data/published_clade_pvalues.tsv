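gene	clownfish_lca	nothobranchius	mole_rat
MTERF1	7.34E-03	1.25E-03	2.57E-02
RARS2	1.82E-03	1.18E-02	NA
MRPL30	2.55E-02	1.00E+00	9.59E-03
FASTKD2	1.77E-04	1.56E-01	1.00E+00
FASTKD5	NA	1.39E-03	8.25E-01
TFB2M	NA	4.34E-04	6.91E-01
NDUFA9	NA	8.31E-02	6.90E-03
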