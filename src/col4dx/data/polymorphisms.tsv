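gene	cdna	protein	consequence_label	maf	published_status	source	carriers	note
COL4A3	c.127G>C	p.Gly43Arg	missense	0.153	polymorphism	literature	F1;F5;F6;F10;F13
COL4A3	c.1721C>T	p.Pro574Leu	missense	0.121	polymorphism	literature	F1;F2;F4;F5;F8;F10;F11;F12;F13;F14;I1;I2
COL4A3	c.3325C>T	p.Pro1109Ser	missense	0.024	polymorphism	literature	F4
COL4A3	c.547-9A>C		intronic	0.024	polymorphism	rs55667591	F3;F4
COL4A3	c.3807C>A	p.Asp1269Glu	missense	0.040	polymorphism	literature	F2;F6
COL4A3	c.976G>T	p.Asp326Tyr	missense	0.226	polymorphism	literature	F3;F6;F7;F8;F11;F13;I3
COL4A3	c.2384-5T>C		intronic	0.113	polymorphism	literature	F7;F10
COL4A3	c.485A>G	p.Glu162Gly	missense	0.798	polymorphism	literature	F1;F2;F3;F4;F5;F6;F7;F8;F9;F10;F11;F12;F13;I1;I2;I3
COL4A3	c.144+12C>A		intronic	0.339	polymorphism	literature	F3;F6;F8;F9;F10;F11;F13;I1;I2;I3
COL4A3	c.422T>C	p.Leu141Pro	missense	0.798	polymorphism	literature	F1;F2;F3;F4;F5;F6;F7;F8;F9;F10;F11;F12;F13;I1;I2;I3
COL4A3	c.1352A>G	p.His451Arg	missense	0.105	polymorphism	literature	F9;I2
COL4A4	c.2717-5A>T		intronic	0.040	polymorphism	literature	F11
COL4A4	c.2501A>G	p.Lys834Arg	missense	0.008	polymorphism	literature	F11
COL4A4	c.4207T>C	p.Ser1403Pro	missense	0.355	polymorphism	literature	F2;F3;F4;F5;F6;F7;F10;F12;I1;I2
COL4A4	c.3817+9G>C		intronic	0.363	polymorphism	literature	F1;F4;F7;F10;F13;I3
COL4A4	c.3979G>A	p.Val1327Met	missense	0.363	polymorphism	literature	F1;F4;F7;F10;F12;F13;I3
COL4A4	c.1444C>T	p.Pro482Ser	missense	0.435	polymorphism	literature	F1;F2;F3;F5;F6;F7;F10;F11;F12;F13;I1;I2
COL4A4	c.3011C>T	p.Pro1004Leu	missense	0.444	polymorphism	literature	F1;F2;F3;F4;F5;F6;F7;F10;F12;F13;I1;I2;I3
COL4A4	c.2996G>A	p.Gly999Glu	missense	0.008	polymorphism	literature	F4	effect uncertain: observed in a young control (age 13, two negative urinalyses) in whom later FBH onset cannot be excluded
COL4A4	c.4394G>A	p.Gly1465Asp	missense		polymorphism	literature	F3	rare variant with uncertain consequence; reported both as polymorphism and as pathogenic; co-segregates with the known pathogenic c.2320G>C in the same family, so its isolated effect cannot be assessed
COL4A5	c.2768-11A>G		intronic	0.065	polymorphism	literature	F3;F10;I1;I2;I3
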