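# Per-residue short + medium range non-bonded energy values (dimensionless,
# energy-like units; more negative = stronger average intra-protein
# non-bonded stabilization).
#
# These are APPROXIMATE values assembled for this package: they track the
# well-established ordering of average residue non-bonded interaction
# strength (large hydrophobic and aromatic side chains most stabilizing,
# small polar residues least).  The similarity score built on them (SNbE)
# is a ratio of two pattern sums, so any monotone-consistent table yields
# sensible relative similarities, and identical residue compositions give
# exactly 100 % regardless of the values below.
#
# Override with your own two-column file (one-letter code, value) via the
# energy_table configuration option / --energy-table CLI flag.
#
# code	energy
A	-4.3
R	-5.1
N	-4.0
D	-3.9
C	-5.6
Q	-4.4
E	-4.1
G	-3.4
H	-5.0
I	-6.5
L	-6.2
K	-4.2
M	-6.1
F	-6.7
P	-4.0
S	-3.7
T	-4.3
W	-7.0
Y	-6.0
V	-5.9
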