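# United-atom heavy-element radii, Å: heavy atoms inflated to absorb the
# hydrogens they carry, for geometry runs on hydrogen-free structures.
C	1.85
N	1.65
O	1.60
P	1.90
S	1.90
FE	2.00
ZN	1.50
MG	1.73
CA	2.31
NA	2.27
K	2.75
CL	1.75
BR	1.85
I	1.98
CU	1.40
MN	2.05
H	1.00
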