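case_id	kind	variants	zygosities
F1	family	COL4A5:c.1094G>A	het
F2	family	COL4A3:c.765G>T	het
F3	family	COL4A4:c.2320G>C;COL4A4:c.1320_1369+2del	het;het
F4	family	COL4A3:c.687G>A;COL4A3:c.3490G>T	het;het
F5	family	COL4A5:c.2395+1G>A	het
F6	family	COL4A5:c.2741G>A	het
F7	family	COL4A5:c.1033-6A>G	het
F8	family	COL4A4:c.1100-2A>C	het
F9	family	COL4A5:c.1780-1G>T	het
F10	family	COL4A5:c.1871G>A	het
F11	family	COL4A5:c.82G>T	het
F12	family	COL4A3:c.765+2T>C	het
F13	family	COL4A3:c.3410G>A	het
F14	family	COL4A5:c.1871G>A	het
I1	individual	COL4A5:c.1010G>T	hemi
I2	individual	COL4A5:c.1871G>A	hemi
I3	individual	COL4A4:c.2986G>A	het
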