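ranking,id,affinity_kcal_mol,ld50_mol_kg,region,pgp
RGZ,RGZ,–8.5,2.713,HIA,-
1,9385738471,–9.3,2.924,Out,-
2,2321610882,–9.1,2.838,BBB,+
3,2772386084,–9.1,2.805,HIA,-
4,1323064686,–9.1,2.781,HIA,+
5,1362639167,–9.0,2.721,BBB,+
6,5835167846,–9.0,2.717,Out,+
7,1302121223,–8.9,2.795,BBB,-
8,1468861772,–8.7,2.774,BBB,-
9,7373425071,–8.7,2.723,Out,-
10,9059019223,–8.6,2.785,BBB,-
11,7585853459,–8.6,2.721,HIA,-
12,8688852980,–8.5,2.796,BBB,-
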