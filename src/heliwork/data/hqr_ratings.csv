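# heliwork handling-qualities rating table, v1
# one row per (test point, pilot) rating; pilots 1-7 are the test-pilot
# panel (groups 1-2), pilots 8-11 the operational panel (group 3)
point_code,pilot_id,group,hqr
B3,1,1,6
B3,2,1,5
B3,6,1,4
B3,4,2,5
B3,3,2,6
B3,7,2,4.5
B3,8,3,6
B3,9,3,6
B3,10,3,5
B3,11,3,6
C1,1,1,5
C1,2,1,4.5
C1,6,1,4
C1,4,2,5
C1,3,2,6
C1,7,2,4
C1,8,3,4.5
C1,9,3,4
C1,10,3,6
C1,11,3,5
C2,1,1,3
C2,2,1,4.5
C2,6,1,5
C2,4,2,5
C2,3,2,5
C2,7,2,5
C2,8,3,6
C2,9,3,4
C2,10,3,6
C2,11,3,3
D1,1,1,8
D1,2,1,7
D1,6,1,6
D1,4,2,6
D1,3,2,8
D1,8,3,8
D1,9,3,9
D1,10,3,7
D1,11,3,8
D2,1,1,5
D2,2,1,4.5
D2,6,1,6
D2,4,2,4
D2,3,2,5
D2,8,3,7
D2,9,3,8
D2,10,3,5
D2,11,3,5
D3,1,1,4
D3,2,1,4
D3,6,1,5
D3,4,2,5
D3,3,2,5
D3,8,3,6
D3,9,3,7
D3,10,3,5
D3,11,3,4
H1,1,1,9
H1,2,1,7
H1,6,1,9
H1,3,2,9
H1,7,2,9
H1,8,3,10
H1,10,3,8
H1,11,3,9
H2,1,1,7
H2,2,1,7
H2,6,1,5
H2,4,2,7
H2,3,2,6
H2,7,2,5
H2,8,3,6
H2,10,3,6
H2,11,3,7
H3,1,1,5
H3,2,1,4
H3,6,1,5
H3,4,2,6
H3,5,2,7
H3,3,2,5
H3,7,2,5
H3,8,3,6
H3,10,3,4
H3,11,3,5
G1,1,1,4.5
G1,2,1,6
G1,6,1,4
G1,4,2,7
G1,5,2,7
G1,3,2,7
G1,7,2,8
G1,9,3,10
G1,10,3,8
G1,11,3,4.5
G2,1,1,4
G2,2,1,4.5
G2,6,1,4
G2,4,2,6
G2,5,2,6
G2,3,2,4.5
G2,7,2,6
G2,9,3,6
G2,10,3,6
G2,11,3,4
G3,1,1,4
G3,2,1,5
G3,6,1,5
G3,4,2,5
G3,5,2,4
G3,7,2,5
G3,8,3,10
G3,9,3,5
G3,10,3,4
G3,11,3,4
F1,1,1,5
F1,2,1,7
F1,6,1,5
F1,4,2,6
F1,5,2,6
F1,3,2,5
F1,9,3,7
F1,11,3,5
F2,1,1,4.5
F2,6,1,4
F2,4,2,5
F2,5,2,6
F2,3,2,4.5
F2,8,3,10
F2,9,3,7
F2,10,3,8
F2,11,3,4.5
F3,1,1,4
F3,2,1,4
F3,6,1,3
F3,5,2,5
F3,3,2,4.5
F3,7,2,5
F3,8,3,4.5
F3,9,3,5
F3,10,3,6
F3,11,3,4
E3B,1,1,4.5
E3B,2,1,4.5
E3B,6,1,5
E3B,4,2,5
E3B,5,2,5
E3B,3,2,4
E3B,7,2,7
E3B,8,3,8
E3B,10,3,6
E3B,11,3,4.5
E4,1,1,8
E4,2,1,6
E4,6,1,7
E4,4,2,7
E4,3,2,8
E4,7,2,8
E4,8,3,8
E4,9,3,9
E4,10,3,9
E4,11,3,8
E5,1,1,3
E5,6,1,4
E5,4,2,4
E5,3,2,3
E5,7,2,5
E5,8,3,5
E5,9,3,4
E5,10,3,4
E5,11,3,3
E3A,1,1,3
E3A,2,1,4
E3A,6,1,5
E3A,4,2,5
E3A,5,2,5
E3A,3,2,3
E3A,7,2,4
E3A,8,3,6
E3A,9,3,6
E3A,10,3,5
E3A,11,3,3
E2,1,1,4
E2,2,1,4
E2,6,1,5
E2,4,2,5
E2,3,2,4
E2,7,2,4.5
E2,8,3,6
E2,9,3,8
E2,10,3,5
E2,11,3,4
E1,1,1,8
E1,2,1,6
E1,6,1,7
E1,4,2,7
E1,3,2,8
E1,7,2,8
E1,8,3,8
E1,9,3,9
E1,10,3,9
E1,11,3,8
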