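# Pair-stacking free energies (kcal/mol) for the simplified nearest-neighbor
# model used by mirseed.rnafold.  Rows: outer pair (5'i . j3'); columns: inner
# pair (i+1 . j-1).  Values are a symmetrized table preserving the canonical
# stability hierarchy GC > AU > GU; the hairpin-loop closure penalty is a
# separate model parameter (default +3.0 kcal/mol).
	AU	UA	GC	CG	GU	UG
AU	-1.2	-1.2	-1.9	-1.9	-1.0	-1.0
UA	-1.2	-1.2	-1.9	-1.9	-1.0	-1.0
GC	-1.9	-1.9	-2.6	-2.6	-1.7	-1.7
CG	-1.9	-1.9	-2.6	-2.6	-1.7	-1.7
GU	-1.0	-1.0	-1.7	-1.7	-0.8	-0.8
UG	-1.0	-1.0	-1.7	-1.7	-0.8	-0.8
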