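# heliwork height-speed test-point catalog, v1
# classical: Outside / Line / Inside / Unlabeled / Excluded
# zone: Take-off / Knee / Cruise / High-hover / Excluded
# height/speed are nominal entry conditions used by the synthetic campaign
# generator; the partition labels are the analysis-relevant content.
code,height_ft,speed_kt,classical,zone
A1,8,0,Excluded,Excluded
B3,20,20,Unlabeled,Take-off
C1,40,30,Outside,Take-off
C2,40,45,Outside,Unzoned
D1,150,30,Inside,Knee
D2,200,40,Line,Knee
D3,250,50,Outside,Knee
H1,100,25,Inside,Knee
H2,120,35,Line,Knee
H3,140,45,Unlabeled,Knee
G1,30,70,Inside,Cruise
G2,50,70,Line,Cruise
G3,80,70,Outside,Cruise
F1,25,85,Inside,Cruise
F2,45,85,Line,Cruise
F3,70,85,Outside,Cruise
E3B,300,55,Inside,Cruise
E4,300,65,Line,Cruise
E5,300,75,Outside,Cruise
E3A,300,0,Inside,High-hover
E2,450,0,Line,High-hover
E1,600,0,Outside,High-hover
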