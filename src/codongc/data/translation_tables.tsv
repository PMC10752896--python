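# NCBI translation tables: the 25 genetic codes known as of Aug 2022.
# Codon order: UUU, UUC, UUA, UUG, UCU, ... GGG (first base slowest; bases U,C,A,G).
# '*' marks a stop signal. 'ambiguities' lists codons whose assignment is
# non-unique (signal set, evenly weighted): dual stop/amino-acid readthrough
# codons per the NCBI table notes (tables 27, 28, 31), and the ascidian
# mitochondrial AGA/AGG Gly/Arg/Ser triple assignment (table 13).
code_id	name	amino_acids	start_codons	ambiguities
1	Standard	FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG	AUG,CUG,UUG	
2	Vertebrate Mitochondrial	FFLLSSSSYY**CCWWLLLLPPPPHHQQRRRRIIMMTTTTNNKKSS**VVVVAAAADDEEGGGG	AUA,AUC,AUG,AUU,GUG	
3	Yeast Mitochondrial	FFLLSSSSYY**CCWWTTTTPPPPHHQQRRRRIIMMTTTTNNKKSSRRVVVVAAAADDEEGGGG	AUA,AUG,GUG	
4	Mold-Protozoan-Coelenterate Mitochondrial and Mycoplasma-Spiroplasma	FFLLSSSSYY**CCWWLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG	AUA,AUC,AUG,AUU,CUG,GUG,UUA,UUG	
5	Invertebrate Mitochondrial	FFLLSSSSYY**CCWWLLLLPPPPHHQQRRRRIIMMTTTTNNKKSSSSVVVVAAAADDEEGGGG	AUA,AUC,AUG,AUU,GUG,UUG	
6	Ciliate-Dasycladacean-Hexamita Nuclear	FFLLSSSSYYQQCC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG	AUG	
9	Echinoderm-Flatworm Mitochondrial	FFLLSSSSYY**CCWWLLLLPPPPHHQQRRRRIIIMTTTTNNNKSSSSVVVVAAAADDEEGGGG	AUG,GUG	
10	Euplotid Nuclear	FFLLSSSSYY**CCCWLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG	AUG	
11	Bacterial-Archaeal-Plant Plastid	FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG	AUA,AUC,AUG,AUU,CUG,GUG,UUG	
12	Alternative Yeast Nuclear	FFLLSSSSYY**CC*WLLLSPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG	AUG,CUG	
13	Ascidian Mitochondrial	FFLLSSSSYY**CCWWLLLLPPPPHHQQRRRRIIMMTTTTNNKKSSGGVVVVAAAADDEEGGGG	AUA,AUG,GUG,UUG	AGA=G|R|S;AGG=G|R|S
14	Alternative Flatworm Mitochondrial	FFLLSSSSYYY*CCWWLLLLPPPPHHQQRRRRIIIMTTTTNNNKSSSSVVVVAAAADDEEGGGG	AUG	
16	Chlorophycean Mitochondrial	FFLLSSSSYY*LCC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG	AUG	
21	Trematode Mitochondrial	FFLLSSSSYY**CCWWLLLLPPPPHHQQRRRRIIMMTTTTNNNKSSSSVVVVAAAADDEEGGGG	AUG,GUG	
22	Scenedesmus obliquus Mitochondrial	FFLLSS*SYY*LCC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG	AUG	
23	Thraustochytrium Mitochondrial	FF*LSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG	AUG,AUU,GUG	
24	Rhabdopleuridae Mitochondrial	FFLLSSSSYY**CCWWLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSSKVVVVAAAADDEEGGGG	AUG,CUG,GUG,UUG	
25	Candidate Division SR1 and Gracilibacteria	FFLLSSSSYY**CCGWLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG	AUG,GUG,UUG	
26	Pachysolen tannophilus Nuclear	FFLLSSSSYY**CC*WLLLAPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG	AUG,CUG	
27	Karyorelict Nuclear	FFLLSSSSYYQQCC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG	AUG	UGA=*|W
28	Condylostoma Nuclear	FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG	AUG	UAA=*|Q;UAG=*|Q;UGA=*|W
29	Mesodinium Nuclear	FFLLSSSSYYYYCC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG	AUG	
30	Peritrich Nuclear	FFLLSSSSYYEECC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG	AUG	
31	Blastocrithidia Nuclear	FFLLSSSSYY**CCWWLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG	AUG	UAA=*|E;UAG=*|E
33	Cephalodiscidae Mitochondrial UAA-Tyr	FFLLSSSSYYY*CCWWLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSSKVVVVAAAADDEEGGGG	AUG,CUG,GUG,UUG	
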