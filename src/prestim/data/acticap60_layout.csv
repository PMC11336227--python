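label,x,y
F7,-1.299041,0.943808
F3,-0.659023,0.813825
Fz,0.000000,0.802851
F4,0.659023,0.813825
F8,1.299041,0.943808
FC5,-1.173172,0.450338
FC1,-0.394923,0.394923
FC2,0.394923,0.394923
FC6,1.173172,0.450338
T7,-1.605703,-0.000000
C3,-0.802851,-0.000000
Cz,0.000000,0.000000
C4,0.802851,0.000000
T8,1.605703,0.000000
TP9,-1.908893,-0.620237
CP5,-1.173172,-0.450338
CP1,-0.394923,-0.394923
CP2,0.394923,-0.394923
CP6,1.173172,-0.450338
TP10,1.908893,-0.620237
P7,-1.299041,-0.943808
P3,-0.659023,-0.813825
Pz,0.000000,-0.802851
P4,0.659023,-0.813825
P8,1.299041,-0.943808
PO9,-1.179761,-1.623801
O1,-0.496189,-1.527114
Oz,0.000000,-1.605703
O2,0.496189,-1.527114
PO10,1.179761,-1.623801
AF7,-0.943808,1.299041
AF3,-0.545830,1.170536
AF4,0.545830,1.170536
AF8,0.943808,1.299041
F5,-0.987913,0.858779
F1,-0.326906,0.809121
F2,0.326906,0.809121
F6,0.987913,0.858779
FT7,-1.527114,0.496189
FC3,-0.775791,0.503804
FC4,0.775791,0.503804
FT8,1.527114,0.496189
C5,-1.204277,-0.000000
C1,-0.401426,-0.000000
C2,0.401426,0.000000
C6,1.204277,0.000000
TP7,-1.527114,-0.496189
CP3,-0.761153,-0.494299
CPz,0.000000,-0.401426
CP4,0.761153,-0.494299
TP8,1.527114,-0.496189
P5,-0.987913,-0.858779
P1,-0.326906,-0.809121
P2,0.326906,-0.809121
P6,0.987913,-0.858779
PO7,-0.943808,-1.299041
PO3,-0.545830,-1.170536
POz,0.000000,-1.204277
PO4,0.545830,-1.170536
PO8,0.943808,-1.299041
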