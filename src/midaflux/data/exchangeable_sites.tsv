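# Effective number of C-H positions per residue that equilibrate with body
# water 2H during protein synthesis (literature-derived in vivo values from
# tracer incorporation studies; real-valued because exchange is partial).
# Columns: one-letter code, n_sites
residue	n_sites
A	4.00
R	3.43
N	1.89
D	1.89
C	1.62
E	3.95
Q	3.95
G	2.06
H	2.88
I	1.00
L	0.60
K	0.54
M	1.12
F	0.32
P	2.59
S	2.61
T	0.20
V	0.56
W	0.08
Y	0.42
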