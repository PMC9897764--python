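# Standard archaeal tRNA gene set: 46 tRNA types, each expected as a
# single-copy gene.  Composition follows the consensus archaeal decoding
# strategy (no A34 wobble anticodons; three distinct CAT isotypes: initiator
# Met, elongator Met, and Ile2) as tabulated for archaeal genomes in GtRNAdb.
isotype	anticodon	expected_copies
Ala	GGC	1
Ala	CGC	1
Ala	TGC	1
Arg	GCG	1
Arg	CCG	1
Arg	TCG	1
Arg	CCT	1
Arg	TCT	1
Asn	GTT	1
Asp	GTC	1
Cys	GCA	1
Gln	CTG	1
Gln	TTG	1
Glu	CTC	1
Glu	TTC	1
Gly	GCC	1
Gly	CCC	1
Gly	TCC	1
His	GTG	1
Ile	GAT	1
Ile2	CAT	1
Leu	CAA	1
Leu	TAA	1
Leu	CAG	1
Leu	TAG	1
Leu	GAG	1
Lys	CTT	1
Lys	TTT	1
Met	CAT	1
iMet	CAT	1
Phe	GAA	1
Pro	GGG	1
Pro	CGG	1
Pro	TGG	1
Ser	GCT	1
Ser	GGA	1
Ser	CGA	1
Ser	TGA	1
Thr	GGT	1
Thr	CGT	1
Thr	TGT	1
Trp	CCA	1
Tyr	GTA	1
Val	GAC	1
Val	CAC	1
Val	TAC	1
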