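# Partial coding-coordinate transcript models.
#
# Exon-end positions are the coding-sequence boundaries that the
# supported variant set itself implies (an intronic description like
# c.765+2 requires an exon ending at c.765; c.547-9 requires an exon
# starting at c.547).  Remaining exon structure is collapsed into the
# final interval up to the CDS length.  Users analysing variants near
# other boundaries should supply a complete model via --config.
transcripts:
  COL4A3:
    cds_length: 5013
    exon_ends: [144, 546, 687, 765, 2383]
  COL4A4:
    cds_length: 5073
    exon_ends: [1099, 1369, 2716, 3817]
  COL4A5:
    cds_length: 5058
    exon_ends: [81, 1032, 1779, 2395, 2767]

# Default collagenous (Gly-X-Y) domain map: one triple-helical interval
# per chain, in protein coordinates.  This is a documented approximation
# (interruptions of the Gly-X-Y repeat are not modelled); results that
# depend on it carry a "domain_map_approximate" flag.
collagenous_domains:
  approximate: true
  intervals:
    COL4A3: [[30, 1450]]
    COL4A4: [[30, 1460]]
    COL4A5: [[42, 1456]]
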