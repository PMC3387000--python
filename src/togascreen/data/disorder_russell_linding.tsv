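# Russell/Linding disorder propensities (Linding et al. 2003, GlobPlot).
# Propensity = relative preference for random coil over regular secondary
# structure; positive values promote disorder, negative values promote
# ordered (globular) structure.
residue	disorder_propensity
A	-0.2615
R	-0.1766
N	0.2299
D	0.2276
C	-0.0183
Q	-0.1877
E	-0.2047
G	0.4332
H	-0.0012
I	-0.4222
L	-0.3379
K	-0.1001
M	-0.2259
F	-0.2256
P	0.5523
S	0.1426
T	0.0089
W	-0.2434
Y	-0.2075
V	-0.3862
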