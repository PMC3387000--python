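# Average amino-acid composition of UniProtKB/Swiss-Prot (release statistics),
# in percent. Used as the default background for the porin composition-bias
# score; normalised to fractions at load time.
residue	percent
A	8.25
R	5.53
N	4.06
D	5.45
C	1.37
Q	3.93
E	6.75
G	7.07
H	2.27
I	5.96
L	9.66
K	5.84
M	2.42
F	3.86
P	4.70
S	6.56
T	5.34
W	1.08
Y	2.92
V	6.87
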