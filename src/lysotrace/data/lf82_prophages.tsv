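# E. coli LF82 prophage annotations.
# Coordinates 1-based inclusive on the LF82 chromosome; the Cyrano
# phage-plasmid is an episome on its own replicon (length nominal, not a
# published value; only mode and copy_number are consumed by analyses).
name	replicon	start	end	mode	pac	copy_number
Gally	chromosome	998954	1037635	integrated	1019224	1
Perceval	chromosome	1172883	1223026	integrated	.	1
Tritos	chromosome	1583925	1630284	integrated	.	1
Cartapus	chromosome	2735987	2769354	integrated	.	1
Cyrano	Cyrano	1	103000	episome	.	5.5
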