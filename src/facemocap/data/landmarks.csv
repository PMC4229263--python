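code,description,side
A,tragus parallel to the upper wall of external acoustic canal,left
a,tragus parallel to the upper wall of external acoustic canal,right
B,central position above the eyebrow,left
b,central position above the eyebrow,right
C,center of the upper eyelid,left
c,center of the upper eyelid,right
D,center of the lower eyelid,left
d,center of the lower eyelid,right
E,angulus oculi temporalis,left
e,angulus oculi temporalis,right
F,angulus oculi medialis,left
f,angulus oculi medialis,right
G,ala of the nose,left
g,ala of the nose,right
H,corner of the mouth,left
h,corner of the mouth,right
I,root of the columella nasi,midline
J,center of eyebrows,midline
K,bony-cartilaginous junction along the nasal dorsum,midline
II,philtrum,midline
III,center of the lower lip,midline
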