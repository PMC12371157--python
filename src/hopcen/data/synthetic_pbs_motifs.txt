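# Synthetic primer-binding-site motif catalog (stand-in sequences; the
# published motifs are available only graphically). One motif per line:
# id <TAB> sequence. PBS motifs are tRNA-complementary, ~14-18 nt.
PBS1	TGGTATCAGAGCCTGG
PBS2	TGGCGCCCAACGTGGG
PBS3	TGGTAGCAGAGGATCG
PBS4	TGGTATCAGAGCGGGC
PBS5	TGGCACCAGTCTTCGG
PBS6	TGGGATCACTCAACGG
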