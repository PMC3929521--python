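exp_no,run_order,A,B,point_type,Y1,Y2,Y3
1,8,-1.00,-1.00,factorial,9.21,2.52,1.6
2,3,1.00,-1.00,factorial,7.64,4.74,1.4
3,4,-1.00,1.00,factorial,8.57,3.11,1.6
4,11,1.00,1.00,factorial,10.41,4.69,1.8
5,10,-1.00,0.00,axial,5.37,7.81,1.2
6,12,1.00,0.00,axial,12.32,5.62,1.1
7,9,0.00,-1.00,axial,6.35,4.59,1.5
8,7,0.00,1.00,axial,5.61,8.25,1.1
9,2,0.00,0.00,centre,4.76,7.64,1.1
10,1,0.00,0.00,centre,4.79,8.01,1.2
11,5,0.00,0.00,centre,4.77,7.78,1.0
12,6,0.00,0.00,centre,4.81,8.11,1.1
13,13,0.00,0.00,centre,4.78,7.85,1.1
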