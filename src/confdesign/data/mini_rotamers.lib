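# synthetic backbone-dependent mini rotamer library
# columns: res phi psi count r1 r2 r3 r4 prob chi1 chi2 chi3 chi4 sig1 sig2 sig3 sig4
ARG -60 -40 100 1 1 1 1 0.4000 -65.0 180.0 65.0 180.0 9.0 10.0 11.0 12.0
ARG -60 -40 100 2 1 1 1 0.3500 180.0 180.0 65.0 180.0 9.0 10.0 11.0 12.0
ARG -60 -40 100 3 1 1 1 0.2500 62.0 180.0 65.0 180.0 9.0 10.0 11.0 12.0
ARG -120 130 100 1 1 1 1 0.4000 -65.0 180.0 65.0 180.0 9.0 10.0 11.0 12.0
ARG -120 130 100 2 1 1 1 0.3500 180.0 180.0 65.0 180.0 9.0 10.0 11.0 12.0
ARG -120 130 100 3 1 1 1 0.2500 62.0 180.0 65.0 180.0 9.0 10.0 11.0 12.0
ASN -60 -40 100 1 1 1 1 0.4000 -65.0 180.0 0.0 0.0 9.0 10.0 11.0 12.0
ASN -60 -40 100 2 1 1 1 0.3500 180.0 180.0 0.0 0.0 9.0 10.0 11.0 12.0
ASN -60 -40 100 3 1 1 1 0.2500 62.0 180.0 0.0 0.0 9.0 10.0 11.0 12.0
ASN -120 130 100 1 1 1 1 0.4000 -65.0 180.0 0.0 0.0 9.0 10.0 11.0 12.0
ASN -120 130 100 2 1 1 1 0.3500 180.0 180.0 0.0 0.0 9.0 10.0 11.0 12.0
ASN -120 130 100 3 1 1 1 0.2500 62.0 180.0 0.0 0.0 9.0 10.0 11.0 12.0
ASP -60 -40 100 1 1 1 1 0.4000 -65.0 180.0 0.0 0.0 9.0 10.0 11.0 12.0
ASP -60 -40 100 2 1 1 1 0.3500 180.0 180.0 0.0 0.0 9.0 10.0 11.0 12.0
ASP -60 -40 100 3 1 1 1 0.2500 62.0 180.0 0.0 0.0 9.0 10.0 11.0 12.0
ASP -120 130 100 1 1 1 1 0.4000 -65.0 180.0 0.0 0.0 9.0 10.0 11.0 12.0
ASP -120 130 100 2 1 1 1 0.3500 180.0 180.0 0.0 0.0 9.0 10.0 11.0 12.0
ASP -120 130 100 3 1 1 1 0.2500 62.0 180.0 0.0 0.0 9.0 10.0 11.0 12.0
CYS -60 -40 100 1 1 1 1 0.4000 -65.0 0.0 0.0 0.0 9.0 10.0 11.0 12.0
CYS -60 -40 100 2 1 1 1 0.3500 180.0 0.0 0.0 0.0 9.0 10.0 11.0 12.0
CYS -60 -40 100 3 1 1 1 0.2500 62.0 0.0 0.0 0.0 9.0 10.0 11.0 12.0
CYS -120 130 100 1 1 1 1 0.4000 -65.0 0.0 0.0 0.0 9.0 10.0 11.0 12.0
CYS -120 130 100 2 1 1 1 0.3500 180.0 0.0 0.0 0.0 9.0 10.0 11.0 12.0
CYS -120 130 100 3 1 1 1 0.2500 62.0 0.0 0.0 0.0 9.0 10.0 11.0 12.0
GLN -60 -40 100 1 1 1 1 0.4000 -65.0 180.0 65.0 0.0 9.0 10.0 11.0 12.0
GLN -60 -40 100 2 1 1 1 0.3500 180.0 180.0 65.0 0.0 9.0 10.0 11.0 12.0
GLN -60 -40 100 3 1 1 1 0.2500 62.0 180.0 65.0 0.0 9.0 10.0 11.0 12.0
GLN -120 130 100 1 1 1 1 0.4000 -65.0 180.0 65.0 0.0 9.0 10.0 11.0 12.0
GLN -120 130 100 2 1 1 1 0.3500 180.0 180.0 65.0 0.0 9.0 10.0 11.0 12.0
GLN -120 130 100 3 1 1 1 0.2500 62.0 180.0 65.0 0.0 9.0 10.0 11.0 12.0
GLU -60 -40 100 1 1 1 1 0.4000 -65.0 180.0 65.0 0.0 9.0 10.0 11.0 12.0
GLU -60 -40 100 2 1 1 1 0.3500 180.0 180.0 65.0 0.0 9.0 10.0 11.0 12.0
GLU -60 -40 100 3 1 1 1 0.2500 62.0 180.0 65.0 0.0 9.0 10.0 11.0 12.0
GLU -120 130 100 1 1 1 1 0.4000 -65.0 180.0 65.0 0.0 9.0 10.0 11.0 12.0
GLU -120 130 100 2 1 1 1 0.3500 180.0 180.0 65.0 0.0 9.0 10.0 11.0 12.0
GLU -120 130 100 3 1 1 1 0.2500 62.0 180.0 65.0 0.0 9.0 10.0 11.0 12.0
HIS -60 -40 100 1 1 1 1 0.4000 -65.0 180.0 0.0 0.0 9.0 10.0 11.0 12.0
HIS -60 -40 100 2 1 1 1 0.3500 180.0 180.0 0.0 0.0 9.0 10.0 11.0 12.0
HIS -60 -40 100 3 1 1 1 0.2500 62.0 180.0 0.0 0.0 9.0 10.0 11.0 12.0
HIS -120 130 100 1 1 1 1 0.4000 -65.0 180.0 0.0 0.0 9.0 10.0 11.0 12.0
HIS -120 130 100 2 1 1 1 0.3500 180.0 180.0 0.0 0.0 9.0 10.0 11.0 12.0
HIS -120 130 100 3 1 1 1 0.2500 62.0 180.0 0.0 0.0 9.0 10.0 11.0 12.0
ILE -60 -40 100 1 1 1 1 0.4000 -65.0 180.0 0.0 0.0 9.0 10.0 11.0 12.0
ILE -60 -40 100 2 1 1 1 0.3500 180.0 180.0 0.0 0.0 9.0 10.0 11.0 12.0
ILE -60 -40 100 3 1 1 1 0.2500 62.0 180.0 0.0 0.0 9.0 10.0 11.0 12.0
ILE -120 130 100 1 1 1 1 0.4000 -65.0 180.0 0.0 0.0 9.0 10.0 11.0 12.0
ILE -120 130 100 2 1 1 1 0.3500 180.0 180.0 0.0 0.0 9.0 10.0 11.0 12.0
ILE -120 130 100 3 1 1 1 0.2500 62.0 180.0 0.0 0.0 9.0 10.0 11.0 12.0
LEU -60 -40 100 1 1 1 1 0.4000 -65.0 180.0 0.0 0.0 9.0 10.0 11.0 12.0
LEU -60 -40 100 2 1 1 1 0.3500 180.0 180.0 0.0 0.0 9.0 10.0 11.0 12.0
LEU -60 -40 100 3 1 1 1 0.2500 62.0 180.0 0.0 0.0 9.0 10.0 11.0 12.0
LEU -120 130 100 1 1 1 1 0.4000 -65.0 180.0 0.0 0.0 9.0 10.0 11.0 12.0
LEU -120 130 100 2 1 1 1 0.3500 180.0 180.0 0.0 0.0 9.0 10.0 11.0 12.0
LEU -120 130 100 3 1 1 1 0.2500 62.0 180.0 0.0 0.0 9.0 10.0 11.0 12.0
LYS -60 -40 100 1 1 1 1 0.4000 -65.0 180.0 65.0 180.0 9.0 10.0 11.0 12.0
LYS -60 -40 100 2 1 1 1 0.3500 180.0 180.0 65.0 180.0 9.0 10.0 11.0 12.0
LYS -60 -40 100 3 1 1 1 0.2500 62.0 180.0 65.0 180.0 9.0 10.0 11.0 12.0
LYS -120 130 100 1 1 1 1 0.4000 -65.0 180.0 65.0 180.0 9.0 10.0 11.0 12.0
LYS -120 130 100 2 1 1 1 0.3500 180.0 180.0 65.0 180.0 9.0 10.0 11.0 12.0
LYS -120 130 100 3 1 1 1 0.2500 62.0 180.0 65.0 180.0 9.0 10.0 11.0 12.0
MET -60 -40 100 1 1 1 1 0.4000 -65.0 180.0 65.0 0.0 9.0 10.0 11.0 12.0
MET -60 -40 100 2 1 1 1 0.3500 180.0 180.0 65.0 0.0 9.0 10.0 11.0 12.0
MET -60 -40 100 3 1 1 1 0.2500 62.0 180.0 65.0 0.0 9.0 10.0 11.0 12.0
MET -120 130 100 1 1 1 1 0.4000 -65.0 180.0 65.0 0.0 9.0 10.0 11.0 12.0
MET -120 130 100 2 1 1 1 0.3500 180.0 180.0 65.0 0.0 9.0 10.0 11.0 12.0
MET -120 130 100 3 1 1 1 0.2500 62.0 180.0 65.0 0.0 9.0 10.0 11.0 12.0
PHE -60 -40 100 1 1 1 1 0.4000 -65.0 180.0 0.0 0.0 9.0 10.0 11.0 12.0
PHE -60 -40 100 2 1 1 1 0.3500 180.0 180.0 0.0 0.0 9.0 10.0 11.0 12.0
PHE -60 -40 100 3 1 1 1 0.2500 62.0 180.0 0.0 0.0 9.0 10.0 11.0 12.0
PHE -120 130 100 1 1 1 1 0.4000 -65.0 180.0 0.0 0.0 9.0 10.0 11.0 12.0
PHE -120 130 100 2 1 1 1 0.3500 180.0 180.0 0.0 0.0 9.0 10.0 11.0 12.0
PHE -120 130 100 3 1 1 1 0.2500 62.0 180.0 0.0 0.0 9.0 10.0 11.0 12.0
SER -60 -40 100 1 1 1 1 0.4000 -65.0 0.0 0.0 0.0 9.0 10.0 11.0 12.0
SER -60 -40 100 2 1 1 1 0.3500 180.0 0.0 0.0 0.0 9.0 10.0 11.0 12.0
SER -60 -40 100 3 1 1 1 0.2500 62.0 0.0 0.0 0.0 9.0 10.0 11.0 12.0
SER -120 130 100 1 1 1 1 0.4000 -65.0 0.0 0.0 0.0 9.0 10.0 11.0 12.0
SER -120 130 100 2 1 1 1 0.3500 180.0 0.0 0.0 0.0 9.0 10.0 11.0 12.0
SER -120 130 100 3 1 1 1 0.2500 62.0 0.0 0.0 0.0 9.0 10.0 11.0 12.0
THR -60 -40 100 1 1 1 1 0.4000 -65.0 0.0 0.0 0.0 9.0 10.0 11.0 12.0
THR -60 -40 100 2 1 1 1 0.3500 180.0 0.0 0.0 0.0 9.0 10.0 11.0 12.0
THR -60 -40 100 3 1 1 1 0.2500 62.0 0.0 0.0 0.0 9.0 10.0 11.0 12.0
THR -120 130 100 1 1 1 1 0.4000 -65.0 0.0 0.0 0.0 9.0 10.0 11.0 12.0
THR -120 130 100 2 1 1 1 0.3500 180.0 0.0 0.0 0.0 9.0 10.0 11.0 12.0
THR -120 130 100 3 1 1 1 0.2500 62.0 0.0 0.0 0.0 9.0 10.0 11.0 12.0
TRP -60 -40 100 1 1 1 1 0.4000 -65.0 180.0 0.0 0.0 9.0 10.0 11.0 12.0
TRP -60 -40 100 2 1 1 1 0.3500 180.0 180.0 0.0 0.0 9.0 10.0 11.0 12.0
TRP -60 -40 100 3 1 1 1 0.2500 62.0 180.0 0.0 0.0 9.0 10.0 11.0 12.0
TRP -120 130 100 1 1 1 1 0.4000 -65.0 180.0 0.0 0.0 9.0 10.0 11.0 12.0
TRP -120 130 100 2 1 1 1 0.3500 180.0 180.0 0.0 0.0 9.0 10.0 11.0 12.0
TRP -120 130 100 3 1 1 1 0.2500 62.0 180.0 0.0 0.0 9.0 10.0 11.0 12.0
TYR -60 -40 100 1 1 1 1 0.4000 -65.0 180.0 0.0 0.0 9.0 10.0 11.0 12.0
TYR -60 -40 100 2 1 1 1 0.3500 180.0 180.0 0.0 0.0 9.0 10.0 11.0 12.0
TYR -60 -40 100 3 1 1 1 0.2500 62.0 180.0 0.0 0.0 9.0 10.0 11.0 12.0
TYR -120 130 100 1 1 1 1 0.4000 -65.0 180.0 0.0 0.0 9.0 10.0 11.0 12.0
TYR -120 130 100 2 1 1 1 0.3500 180.0 180.0 0.0 0.0 9.0 10.0 11.0 12.0
TYR -120 130 100 3 1 1 1 0.2500 62.0 180.0 0.0 0.0 9.0 10.0 11.0 12.0
VAL -60 -40 100 1 1 1 1 0.4000 -65.0 0.0 0.0 0.0 9.0 10.0 11.0 12.0
VAL -60 -40 100 2 1 1 1 0.3500 180.0 0.0 0.0 0.0 9.0 10.0 11.0 12.0
VAL -60 -40 100 3 1 1 1 0.2500 62.0 0.0 0.0 0.0 9.0 10.0 11.0 12.0
VAL -120 130 100 1 1 1 1 0.4000 -65.0 0.0 0.0 0.0 9.0 10.0 11.0 12.0
VAL -120 130 100 2 1 1 1 0.3500 180.0 0.0 0.0 0.0 9.0 10.0 11.0 12.0
VAL -120 130 100 3 1 1 1 0.2500 62.0 0.0 0.0 0.0 9.0 10.0 11.0 12.0
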