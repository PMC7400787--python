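# Synthetic UV mutational signature (192 strand-resolved channels).
# Constructed from the qualitative photochemistry of UV mutagenesis:
# C->T at dipyrimidine sites dominates, with a 5x transcriptional strand
# bias against purine-reference (reciprocal strand) channels; the single
# literature-pinned channel probability TCC->TTC = 0.2887 is exact.
# This is NOT a published signature table.
ctx5	ref	alt	ctx3	prob
A	A	C	A	0.0001052841918
A	A	C	C	0.0001052841918
A	A	C	G	0.0001052841918
A	A	C	T	0.0001052841918
A	A	G	A	0.0008422735346
A	A	G	C	0.0002105683837
A	A	G	G	0.0008422735346
A	A	G	T	0.0002105683837
A	A	T	A	0.0002105683837
A	A	T	C	0.0002105683837
A	A	T	G	0.0002105683837
A	A	T	T	0.0002105683837
A	C	A	A	0.001473978686
A	C	A	C	0.002526820604
A	C	A	G	0.001052841918
A	C	A	T	0.002105683837
A	C	G	A	0.0007369893428
A	C	G	C	0.001263410302
A	C	G	G	0.0005264209591
A	C	G	T	0.001052841918
A	C	T	A	0.004421936057
A	C	T	C	0.007580461812
A	C	T	G	0.003158525755
A	C	T	T	0.00631705151
A	G	A	A	0.02105683837
A	G	A	C	0.001263410302
A	G	A	G	0.0115812611
A	G	A	T	0.001263410302
A	G	C	A	0.0002105683837
A	G	C	C	0.0002105683837
A	G	C	G	0.0002105683837
A	G	C	T	0.0002105683837
A	G	T	A	0.0004211367673
A	G	T	C	0.0004211367673
A	G	T	G	0.0004211367673
A	G	T	T	0.0004211367673
A	T	A	A	0.0007369893428
A	T	A	C	0.001263410302
A	T	A	G	0.0005264209591
A	T	A	T	0.001052841918
A	T	C	A	0.0007369893428
A	T	C	C	0.001263410302
A	T	C	G	0.0005264209591
A	T	C	T	0.001052841918
A	T	G	A	0.0003684946714
A	T	G	C	0.000631705151
A	T	G	G	0.0002632104796
A	T	G	T	0.0005264209591
C	A	C	A	5.264209591e-05
C	A	C	C	5.264209591e-05
C	A	C	G	5.264209591e-05
C	A	C	T	5.264209591e-05
C	A	G	A	0.0004211367673
C	A	G	C	0.0001052841918
C	A	G	G	0.0004211367673
C	A	G	T	0.0001052841918
C	A	T	A	0.0001052841918
C	A	T	C	0.0001052841918
C	A	T	G	0.0001052841918
C	A	T	T	0.0001052841918
C	C	A	A	0.001473978686
C	C	A	C	0.002526820604
C	C	A	G	0.001052841918
C	C	A	T	0.002105683837
C	C	G	A	0.0007369893428
C	C	G	C	0.001263410302
C	C	G	G	0.0005264209591
C	C	G	T	0.001052841918
C	C	T	A	0.04053441385
C	C	T	C	0.06948756661
C	C	T	G	0.02895315275
C	C	T	T	0.05790630551
C	G	A	A	0.01052841918
C	G	A	C	0.000631705151
C	G	A	G	0.005790630551
C	G	A	T	0.000631705151
C	G	C	A	0.0001052841918
C	G	C	C	0.0001052841918
C	G	C	G	0.0001052841918
C	G	C	T	0.0001052841918
C	G	T	A	0.0002105683837
C	G	T	C	0.0002105683837
C	G	T	G	0.0002105683837
C	G	T	T	0.0002105683837
C	T	A	A	0.0007369893428
C	T	A	C	0.001263410302
C	T	A	G	0.0005264209591
C	T	A	T	0.001052841918
C	T	C	A	0.002947957371
C	T	C	C	0.005053641208
C	T	C	G	0.002105683837
C	T	C	T	0.004211367673
C	T	G	A	0.0003684946714
C	T	G	C	0.000631705151
C	T	G	G	0.0002632104796
C	T	G	T	0.0005264209591
G	A	C	A	0.0001263410302
G	A	C	C	0.0001263410302
G	A	C	G	0.0001263410302
G	A	C	T	0.0001263410302
G	A	G	A	0.001010728242
G	A	G	C	0.0002526820604
G	A	G	G	0.001010728242
G	A	G	T	0.0002526820604
G	A	T	A	0.0002526820604
G	A	T	C	0.0002526820604
G	A	T	G	0.0002526820604
G	A	T	T	0.0002526820604
G	C	A	A	0.001473978686
G	C	A	C	0.002526820604
G	C	A	G	0.001052841918
G	C	A	T	0.002105683837
G	C	G	A	0.0007369893428
G	C	G	C	0.001263410302
G	C	G	G	0.0005264209591
G	C	G	T	0.001052841918
G	C	T	A	0.004421936057
G	C	T	C	0.007580461812
G	C	T	G	0.003158525755
G	C	T	T	0.00631705151
G	G	A	A	0.02526820604
G	G	A	C	0.001516092362
G	G	A	G	0.01389751332
G	G	A	T	0.001516092362
G	G	C	A	0.0002526820604
G	G	C	C	0.0002526820604
G	G	C	G	0.0002526820604
G	G	C	T	0.0002526820604
G	G	T	A	0.0005053641208
G	G	T	C	0.0005053641208
G	G	T	G	0.0005053641208
G	G	T	T	0.0005053641208
G	T	A	A	0.0007369893428
G	T	A	C	0.001263410302
G	T	A	G	0.0005264209591
G	T	A	T	0.001052841918
G	T	C	A	0.0007369893428
G	T	C	C	0.001263410302
G	T	C	G	0.0005264209591
G	T	C	T	0.001052841918
G	T	G	A	0.0003684946714
G	T	G	C	0.000631705151
G	T	G	G	0.0002632104796
G	T	G	T	0.0005264209591
T	A	C	A	7.369893428e-05
T	A	C	C	7.369893428e-05
T	A	C	G	7.369893428e-05
T	A	C	T	7.369893428e-05
T	A	G	A	0.0005895914742
T	A	G	C	0.0001473978686
T	A	G	G	0.0005895914742
T	A	G	T	0.0001473978686
T	A	T	A	0.0001473978686
T	A	T	C	0.0001473978686
T	A	T	G	0.0001473978686
T	A	T	T	0.0001473978686
T	C	A	A	0.001473978686
T	C	A	C	0.002526820604
T	C	A	G	0.001052841918
T	C	A	T	0.002105683837
T	C	G	A	0.0007369893428
T	C	G	C	0.001263410302
T	C	G	G	0.0005264209591
T	C	G	T	0.001052841918
T	C	T	A	0.07369893428
T	C	T	C	0.2887
T	C	T	G	0.05264209591
T	C	T	T	0.1052841918
T	G	A	A	0.01473978686
T	G	A	C	0.0008843872114
T	G	A	G	0.008106882771
T	G	A	T	0.0008843872114
T	G	C	A	0.0001473978686
T	G	C	C	0.0001473978686
T	G	C	G	0.0001473978686
T	G	C	T	0.0001473978686
T	G	T	A	0.0002947957371
T	G	T	C	0.0002947957371
T	G	T	G	0.0002947957371
T	G	T	T	0.0002947957371
T	T	A	A	0.0007369893428
T	T	A	C	0.001263410302
T	T	A	G	0.0005264209591
T	T	A	T	0.001052841918
T	T	C	A	0.002947957371
T	T	C	C	0.005053641208
T	T	C	G	0.002105683837
T	T	C	T	0.004211367673
T	T	G	A	0.0003684946714
T	T	G	C	0.000631705151
T	T	G	G	0.0002632104796
T	T	G	T	0.0005264209591
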