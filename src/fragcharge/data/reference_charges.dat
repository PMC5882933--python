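# Reference partial charges, elementary charge units.
# Format: RESNAME ATOMNAME CHARGE
# Amber-like magnitudes, constructed so that every residue sums exactly to
# its formal charge (neutral residues 0, GLU -1, LYS +1).  Terminal patches
# (NTERM_*/CTERM_*) replace the listed backbone atoms of the first/last
# residue of a chain segment; the patch sums keep per-residue totals exact.
ALA N    -0.40
ALA H     0.25
ALA CA    0.05
ALA HA    0.10
ALA CB   -0.30
ALA HB1   0.10
ALA HB2   0.10
ALA HB3   0.10
ALA C     0.55
ALA O    -0.55
GLY N    -0.40
GLY H     0.25
GLY CA   -0.05
GLY HA2   0.10
GLY HA3   0.10
GLY C     0.55
GLY O    -0.55
SER N    -0.40
SER H     0.25
SER CA    0.05
SER HA    0.10
SER CB    0.20
SER HB2   0.05
SER HB3   0.05
SER OG   -0.65
SER HG    0.35
SER C     0.55
SER O    -0.55
VAL N    -0.40
VAL H     0.25
VAL CA    0.05
VAL HA    0.10
VAL CB   -0.10
VAL HB    0.10
VAL CG1  -0.27
VAL HG11  0.09
VAL HG12  0.09
VAL HG13  0.09
VAL CG2  -0.27
VAL HG21  0.09
VAL HG22  0.09
VAL HG23  0.09
VAL C     0.55
VAL O    -0.55
GLU N    -0.40
GLU H     0.25
GLU CA    0.05
GLU HA    0.10
GLU CB   -0.10
GLU HB2   0.05
GLU HB3   0.05
GLU CG   -0.10
GLU HG2   0.05
GLU HG3   0.05
GLU CD    0.60
GLU OE1  -0.80
GLU OE2  -0.80
GLU C     0.55
GLU O    -0.55
LYS N    -0.40
LYS H     0.25
LYS CA    0.05
LYS HA    0.10
LYS CB   -0.10
LYS HB2   0.05
LYS HB3   0.05
LYS CG   -0.10
LYS HG2   0.05
LYS HG3   0.05
LYS CD   -0.10
LYS HD2   0.05
LYS HD3   0.05
LYS CE    0.20
LYS HE2   0.10
LYS HE3   0.10
LYS NZ   -0.60
LYS HZ1   0.40
LYS HZ2   0.40
LYS HZ3   0.40
LYS C     0.55
LYS O    -0.55
# Neutral N-terminus: NH2 replaces backbone N/H. Sum -0.15 matches N+H.
NTERM_NEUTRAL N  -0.75
NTERM_NEUTRAL H1  0.30
NTERM_NEUTRAL H2  0.30
# Zwitterionic N-terminus: NH3+ (adds +1 to the residue formal charge).
NTERM_ZWIT N  -0.35
NTERM_ZWIT H1  0.40
NTERM_ZWIT H2  0.40
NTERM_ZWIT H3  0.40
# Neutral C-terminus: COOH replaces backbone C/O. Sum 0.00 matches C+O.
CTERM_NEUTRAL C    0.60
CTERM_NEUTRAL O   -0.55
CTERM_NEUTRAL OXT -0.60
CTERM_NEUTRAL HXT  0.55
# Zwitterionic C-terminus: COO- (adds -1 to the residue formal charge).
CTERM_ZWIT C    0.55
CTERM_ZWIT O   -0.775
CTERM_ZWIT OXT -0.775
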