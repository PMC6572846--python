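clade	Mainland Japanese	Korean	JPT	CHB	CHS	CDX	KHV
clade1	0.354	0	0.357	0	0	0	0
clade2	0.354	0.298	0.357	0.261	0.192	0.682	0.391
clade3	0.197	0.362	0.179	0.500	0.769	0.295	0.457
clade4	0.041	0.064	0.071	0	0	0	0
clade5	0.041	0.149	0.036	0.065	0.019	0.023	0.022
clade6	0.009	0.085	0	0.130	0	0	0.043
clade7	0.006	0.043	0	0.022	0	0	0.043
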