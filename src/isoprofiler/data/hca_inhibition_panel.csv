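compound_id,isoform,ki_nm
1,hCA_I,7.3
1,hCA_II,1.4
1,hCA_IX,67.7
1,hCA_XII,716.5
2,hCA_I,1023.0
2,hCA_II,11.6
2,hCA_IX,713.1
2,hCA_XII,30.6
3,hCA_I,>100000
3,hCA_II,>100000
3,hCA_IX,>100000
3,hCA_XII,>100000
4,hCA_I,36.2
4,hCA_II,6.8
4,hCA_IX,2523.8
4,hCA_XII,603.0
5,hCA_I,>100000
5,hCA_II,>100000
5,hCA_IX,>100000
5,hCA_XII,>100000
6,hCA_I,>100000
6,hCA_II,7050.3
6,hCA_IX,>100000
6,hCA_XII,>100000
7,hCA_I,2858.1
7,hCA_II,9.8
7,hCA_IX,6826.7
7,hCA_XII,350.9
8,hCA_I,1204.8
8,hCA_II,23.9
8,hCA_IX,715.4
8,hCA_XII,832.5
9,hCA_I,212.6
9,hCA_II,443.6
9,hCA_IX,728.5
9,hCA_XII,568.4
10,hCA_I,31589
10,hCA_II,>100000
10,hCA_IX,>100000
10,hCA_XII,>100000
11,hCA_I,665.6
11,hCA_II,16.4
11,hCA_IX,73.7
11,hCA_XII,49.4
12,hCA_I,1076.3
12,hCA_II,151.4
12,hCA_IX,313.2
12,hCA_XII,648.1
AAZ,hCA_I,250.0
AAZ,hCA_II,12.1
AAZ,hCA_IX,25.3
AAZ,hCA_XII,5.7
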