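# Standardized facial expressions: one row per (expression, active landmark).
# dx/dy/dz are synthetic peak displacements (mm) in the anatomical frame
# (X left "+", Y up "+", Z forward "+"); the published protocol names the
# movements but not their amplitudes, so magnitudes here are design choices.
index,name,landmark,dx_mm,dy_mm,dz_mm
1,Maximal brow lift,B,0,8,0
1,Maximal brow lift,b,0,8,0
1,Maximal brow lift,J,0,7,0
2,Light eye closure,C,0,-4,0
2,Light eye closure,c,0,-4,0
3,Maximally tight eye closure,C,0,-6,0
3,Maximally tight eye closure,c,0,-6,0
3,Maximally tight eye closure,D,0,2,0
3,Maximally tight eye closure,d,0,2,0
3,Maximally tight eye closure,B,0,-3,0
3,Maximally tight eye closure,b,0,-3,0
4,Maximally frown,B,-2,-5,0
4,Maximally frown,b,2,-5,0
4,Maximally frown,J,0,-6,0
4,Maximally frown,F,-1,-2,0
4,Maximally frown,f,1,-2,0
5,Maximally showing teeth,H,4,1,-3
5,Maximally showing teeth,h,-4,1,-3
5,Maximally showing teeth,II,0,-3,-1
5,Maximally showing teeth,III,0,-6,-2
6,move right mouth corner to right-back,h,-8,0,-4
7,move left mouth corner to left-back,H,8,0,-4
8,maximal jaw drop,III,0,-20,-4
8,maximal jaw drop,II,0,-6,-2
8,maximal jaw drop,H,0,-6,-2
8,maximal jaw drop,h,0,-6,-2
9,Smile(showing at least 8 upper teeth),H,6,4,-3
9,Smile(showing at least 8 upper teeth),h,-6,4,-3
9,Smile(showing at least 8 upper teeth),II,0,1,-1
9,Smile(showing at least 8 upper teeth),III,0,2,-1
10,Maximal pucker,H,-6,-1,5
10,Maximal pucker,h,6,-1,5
10,Maximal pucker,II,0,-2,6
10,Maximal pucker,III,0,2,6
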