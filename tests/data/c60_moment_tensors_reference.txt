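# Published reference moment-tensor components for a C60 cage
# (radius ~3.547 A; fitted values, body frame). rank  location  value
0  G0  60
1  G1  0.00000
1  G2  0.00002
1  G3  0.00002
2  G4  251.57483
2  G5  0.00871
2  G6  0.02755
2  G7  251.57513
2  G8  -0.03941
2  G9  251.6387
3  G10  0.00190
3  G11  0.00288
3  G12  -0.00735
3  G13  -0.00382
3  G14  -0.00095
3  G15  0.00172
3  G16  0.01110
3  G17  -0.00650
3  G18  -0.01328
3  G19  0.01462
4  G20  1898.65174
4  G21  -0.08173
4  G22  0.23940
4  G23  632.88311
4  G24  -0.12178
4  G25  633.07361
4  G26  -0.07104
4  G27  0.07556
4  G28  0.02058
4  G29  0.23205
4  G30  1898.67454
4  G31  -0.34235
4  G32  633.05680
4  G33  -0.31836
4  G34  1899.74600
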