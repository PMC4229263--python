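# Synthetic rest-pose face template, head-fixed frame, millimetres.
# Axes: X left "+", Y up "+", Z forward "+" (toward the cameras).
# Mirror symmetry: lowercase (right-side) landmarks are the uppercase
# (left-side) homologues with X negated. HM1-HM3 are the rigid helmet markers.
code,x_mm,y_mm,z_mm
A,72,0,0
a,-72,0,0
B,32,48,78
b,-32,48,78
C,32,28,82
c,-32,28,82
D,32,18,82
d,-32,18,82
E,45,24,70
e,-45,24,70
F,17,25,80
f,-17,25,80
G,18,-12,92
g,-18,-12,92
H,26,-38,82
h,-26,-38,82
I,0,0,98
J,0,50,88
K,0,25,95
II,0,-28,90
III,0,-48,85
HM1,0,110,70
HM2,40,85,20
HM3,-40,85,20
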