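# Library-scale read totals reported for the Tibetan naked carp small-RNA
# sequencing (four pooled replicate libraries); used as demonstration
# inputs for the cleaning-statistics bookkeeping.
quantity	value
raw_reads	60037248
clean_reads	47030422
clean_percent_printed	78.34
length_filtered_reads	37552615
unique_sequences	564579
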