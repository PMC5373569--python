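# Conserved miRNA family-size distribution reported for the Tibetan naked
# carp (Gymnocypris przewalskii) miRNAome; used as a demonstration input
# for family-size bookkeeping.  Columns: family size, number of families.
size	n_families
1	63
2	45
3	6
4	20
5	6
6	5
7	2
8	2
9	1
10	2
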