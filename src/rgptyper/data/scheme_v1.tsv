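# rgp-scheme/1
# Typing scheme for the Streptococcus thermophilus Rgp (rhamnose-glucose
# polysaccharide) locus.  Primers are written 5'->3'.  Sections are introduced
# by a [section] line; fields are tab-separated.
#
# [pairs] columns:
#   name     pair identifier (primer names are derived as <name>F / <name>R)
#   panel    classification | multiplex1 | multiplex2 | multiplex
#            ("multiplex" marks the control pair shared by both multiplex panels)
#   control  yes|no  (RGPpos is the control of the classification panel)
#   forward  forward primer sequence
#   reverse  reverse primer sequence
#   amplicon expected product size in bp (inclusive span, forward 5' base
#            through reverse-priming-site 3' base)
#   targets  comma-separated Rgp group labels the pair amplifies ("all" = every group)
[pairs]
RGPpos	classification	yes	CAGGTGCAAATGGCCAACTCG	CTTGCCATGTTGGGATGAC	801	all
RGPgroup1	classification	no	GGATGATGGTTCGACGGATAG	CCGCTCTTCCAAAACCATGA	631	1
RGPgroup2	classification	no	GTGAAGAGTCAGAAGACGAAT	CAAAGGCCCCGATGGTATT	464	2
RGPgroup3	classification	no	GAGGAAGCAACAGATAAACGA	GACCAATTGGTCCACAAAAGT	303	3
RGPgroup4	classification	no	CTCCTCGTACTCACCCAC	GCACAAGATACAGCTCGTTAC	162	4
MSControl	multiplex	yes	GCTGGTCGTAATTACCTCG	CAACATCTTCCAAGGTACG	2724	all
Var1	multiplex1	no	GTATATAATGCACAAGAGGG	GAAACTAATCTTAAGCGTTCC	895	1,2
Var2	multiplex1	no	GGAACCATTGAAGTAAGG	CTTTCAGACCTAACATTTGAC	546	2A
Var3	multiplex1	no	GCTTCCAGATGCAAAAACG	GTGTTACTATCATGGCAAG	271	3,4
Var4	multiplex1	no	GTGAAGAATGTAGATGACC	CAATAACAAGTGCTAAGAC	1086	6
Var5	multiplex1	no	CCCCATTGGAGGATATACGCAG	TGGGTAGTACGGTTCGTCAC	376	7
Fg1	multiplex2	no	GTCATGTGCTCTACCAATTG	GATGGAGCTTATAACGTTC	1481	1,6,7
Fg2	multiplex2	no	GTCTTTCATACCATCCATG	GTTCAACTGCTTATTATCG	1040	2,2A,3
Fg3	multiplex2	no	GCTTGGCATGATGGTATG	GAATAACATCACGTCCTCG	852	4,5

# variable-chain type called by each multiplex-1 pair
[vt_map]
Var1	Vt1
Var2	Vt2
Var3	Vt3
Var4	Vt4
Var5	Vt5

# rhamnan-backbone (rgpF) type called by each multiplex-2 pair
[bt_map]
Fg1	Bt1
Fg2	Bt2
Fg3	Bt3

# observed V x B combinations and the overall Rgp group each maps to;
# combinations absent from this table resolve to "novel"
[binomial_map]
V1B1	1
V1B2	2
V2B2	2A
V3B2	3
V3B3	4
V4B1	6
V5B1	7

# single-step legacy classification pairs
[legacy_map]
RGPgroup1	1
RGPgroup2	2
RGPgroup3	3
RGPgroup4	4
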