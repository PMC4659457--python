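site_id,lys_chain,lys_uniprot,lys_helical,arg_chain,arg_uniprot,arg_helical,delta_h,excluded
1,A1B,226,59,A1A,229,62,,True
2,A2,183,87,A1B,257,90,-13.572,False
3,A1B,419,252,A2,348,252,38.54,False
4,A2,386,290,A1A,458,291,7.883,False
5,A1B,494,327,A2,419,323,39.176,False
6,A1A,509,342,A2,438,342,4.357,False
7,A1A,527,360,A2,456,360,-2.304,False
8,A2,516,420,A1A,587,420,43.326,False
9,A2,549,453,A1A,620,453,76.636,False
10,A1B,646,479,A2,579,483,4.076,False
11,A1B,731,564,A1A,734,567,23.157,False
12,A1A,740,573,A2,669,573,19.280,False
13,A1A,748,581,A2,677,581,-23.968,False
14,A1B,770,603,A2,699,603,73.645,False
15,A1B,851,684,A1A,854,687,92.728,False
16,A1A,896,729,A2,825,729,55.401,False
17,A1A,958,791,A1B,956,789,-2.315,False
18,A1A,958,791,A2,884,788,65.516,False
19,A1B,1022,855,A1A,1025,858,16.130,False
20,A2,980,884,A1A,1055,888,-34.501,False
21,A1A,1085,918,A1B,1082,915,21.912,False
22,A2,1020,924,A1A,1094,927,-36.130,False
23,A2,1029,933,A1A,1100,933,,True
24,A1A,1141,974,A2,1073,977,90.852,False
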