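gene	cdna	protein	consequence_label	secondary_splice	cases	published_status	source
COL4A3	c.687G>A		splice_region_exonic	0	F4	none
COL4A3	c.3490G>T	p.Gly1164Cys	missense	0	F4	none
COL4A3	c.765+2T>C		splice_donor	0	F12	none
COL4A3	c.3410G>A	p.Gly1137Asp	missense	0	F13	none
COL4A3	c.765G>T		splice_region_exonic	0	F2	none
COL4A4	c.2320G>C	p.Gly774Arg	missense	0	F3	pathogenic	literature
COL4A4	c.2986G>A	p.Gly996Arg	missense	0	I3	none
COL4A4	c.1100-2A>C		splice_acceptor	0	F8	none
COL4A4	c.1320_1369+2del		deletion_with_splice	0	F3	none
COL4A5	c.1780-1G>T		splice_acceptor	0	F9	none
COL4A5	c.1871G>A	p.Gly624Asp	missense	0	F10;F14;I2	pathogenic	literature
COL4A5	c.1033-6A>G		splice_region_intronic	0	F7	none
COL4A5	c.2395+1G>A		splice_donor	0	F5	none
COL4A5	c.1094G>A	p.Gly365Glu	missense	0	F1	pathogenic	literature
COL4A5	c.2741G>A	p.Gly914Asp	missense	0	F6	none
COL4A5	c.82G>T	p.Ala28Ser	missense	1	F11	none
COL4A5	c.1010G>T	p.Gly337Val	missense	0	I1	none
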