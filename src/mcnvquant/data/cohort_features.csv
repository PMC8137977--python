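patient_id,age_years,sex,eye,se_diopters,overall_pattern,exuberant_capillaries,anastomoses_loops,hypointense_halo,feeder_vessel
1,58,F,L,-13.00,OI,Y,Y,N,Y
2,47,M,R,-15.50,OI,Y,Y,Y,N
3,67,F,R,-7.13,OI,Y,Y,Y,Y
4,52,F,R,-13.50,OI,Y,Y,Y,N
5,50,F,L,-12.63,OI,Y,Y,N,N
6,50,M,R,-10.88,OI,Y,Y,Y,Y
7,30,F,L,-13.50,OI,Y,Y,Y,Y
8,51,M,R,NA,OI,Y,Y,N,N
8,51,M,L,NA,DVL,N,Y,N,N
9,49,F,L,-13.25,OI,Y,Y,Y,N
10,31,F,L,-6.50,OI,Y,Y,Y,N
11,43,M,R,-7.75,OI,Y,Y,Y,Y
11,43,M,L,-9.13,OI,Y,Y,Y,N
12,25,F,L,-8.50,OI,Y,Y,Y,N
13,53,F,L,-8.50,OI,Y,Y,Y,N
14,57,F,R,-17.00,OI,Y,Y,Y,N
15,49,M,R,-14.75,OI,Y,Y,Y,N
16,37,M,L,-8.00,OI,Y,Y,Y,Y
17,35,M,L,-13.50,DVL,N,Y,Y,N
18,60,F,R,-15.50,OI,Y,Y,Y,N
19,30,F,L,-11.75,OI,Y,Y,Y,N
20,62,M,R,-11.25,OI,Y,Y,Y,N
21,28,F,L,-11.13,OI,Y,Y,Y,N
22,31,M,L,-7.00,OI,Y,Y,Y,N
23,34,F,L,-7.63,DVL,N,Y,N,N
24,58,F,L,-12.25,OI,Y,Y,Y,N
25,29,M,R,-9.88,DVL,N,N,N,N
26,35,M,R,-13.75,DVL,N,Y,Y,N
27,46,M,R,-18.00,OI,Y,Y,Y,N
28,27,F,R,-17.00,OI,Y,Y,Y,N
29,66,F,L,-10.75,OI,Y,Y,Y,N
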