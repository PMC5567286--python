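# Nearest-neighbor RNA duplex stack free energies, kcal/mol at 37 C.
# Key: 5'XY3' (miRNA strand) over 3'WZ5' (target strand), written XY/WZ;
# X:W and Y:Z must each be Watson-Crick or G:U. Edit to swap parameter sets.
stack	dg37
INIT	4.09
AA/UU	-0.93
AC/UG	-2.24
AG/UC	-2.08
AG/UU	-0.55
AU/UA	-1.10
AU/UG	-1.36
CA/GU	-2.11
CC/GG	-3.26
CG/GC	-2.36
CG/GU	-1.41
CU/GA	-2.08
CU/GG	-2.11
GA/CU	-2.35
GA/UU	-1.00
GC/CG	-3.42
GC/UG	-2.51
GG/CC	-3.26
GG/CU	-1.80
GG/UC	-2.11
GG/UU	0.47
GU/CA	-2.24
GU/CG	-2.51
GU/UA	-1.36
GU/UG	-0.50
UA/AU	-1.33
UA/GU	-1.27
UC/AG	-2.35
UC/GG	-1.80
UG/AC	-2.11
UG/AU	-1.27
UG/GC	-1.41
UG/GU	0.30
UU/AA	-0.93
UU/AG	-1.00
UU/GA	-0.55
UU/GG	0.47
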