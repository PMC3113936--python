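# Codon translation-speed classes for the codon-specific activation step.
# Class A/B/C map to the activation rates k_transA/B/C (35, 8, 4.5 /s by
# default).  The grouping shipped here is a bundled default derived from
# relative codon usage (frequently used codons are read by abundant tRNAs and
# translate fast): usage >= ~20/1000 -> A, < ~8/1000 -> C, otherwise B.
# GAG is placed in class C: it is the canonical slow-to-translate codon used
# in the engineered slow-stretch constructs the fixtures emulate.
# The table must cover all 64 codons; the three stop codons are marked
# "stop" (termination is handled by the completion reaction, not by class
# rates).  Edit freely; any codon may alternatively be given an explicit
# rate through the simulation parameters.
codon	class
TTT	A
TTC	B
TTA	B
TTG	B
CTT	B
CTC	B
CTA	C
CTG	A
ATT	A
ATC	A
ATA	C
ATG	A
GTT	B
GTC	B
GTA	B
GTG	A
TCT	B
TCC	B
TCA	C
TCG	B
CCT	C
CCC	C
CCA	B
CCG	A
ACT	B
ACC	A
ACA	C
ACG	B
GCT	B
GCC	A
GCA	A
GCG	A
TAT	B
TAC	B
TAA	stop
TAG	stop
CAT	B
CAC	B
CAA	B
CAG	A
AAT	B
AAC	A
AAA	A
AAG	B
GAT	A
GAC	B
GAA	A
GAG	C
TGT	C
TGC	C
TGA	stop
TGG	B
CGT	A
CGC	A
CGA	C
CGG	C
AGT	B
AGC	B
AGA	C
AGG	C
GGT	A
GGC	A
GGA	B
GGG	B
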