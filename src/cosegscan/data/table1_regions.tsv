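Chr	Locus	Start	End	Length
2	2q22.3-35	146360626	221800201	75439575
3	3p11.2-q11.2	87373894	94512868	7138974
3	3q13.3-q25.31	119442572	159239866	39797294
4	4q13.1-4q22.3	60013919	96704454	36690535
5	5p15.33-5p15.2	2346621	10752315	8405694
6	6q26-27	162736476	168554222	5817746
8	8q24.23-24.3	138970102	143270729	4300627
8	8p22-q13.1	14253354	68723609	54470255
9	9q21.32-q34.11	83858558	138149166	54290608
10	10p15.3-p14	135708	8638235	8502527
11	11p14.3-q24	21234023	128206410	106972387
12	12p13-q23.3	661031	67262352	66601321
14	14q12-q31.2	22645683	88752821	66107138
15	15q15.1-q26.1	40509600	94077313	53567713
17	17p12-q25.3	9078327	77698582	68620255
19	19p12-q21	23446279	28836326	5390047
20	20q13.13-q13.33	47050483	60111743	13061260
21	21q11.2-q22.12	14687571	38082812	23395241
22	22q11.2-q13.2	16079545	44595591	28516046
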