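# Approximate DraNramp 14-segment definition (SYNTHETIC stand-in).
# Boundaries are anchored on the conserved helix-breaking elements of the fold
# (the TM1 DPGN motif at 56-59, the TM6 MPH motif at 230-232, and the TM10
# proline P386) with typical ~20-25 residue TM spans; they are NOT taken from
# the helix annotations of any deposited structure. Replace with a
# structure-derived definition for publication-grade segment boundaries.
# Columns: name, chain (informational), start, end; 1-based inclusive, author numbering.
name	chain	start	end
TM1a	A	45	55
TM1b	A	60	78
TM2	A	83	110
TM3	A	115	141
TM4	A	150	174
TM5	A	176	200
TM6a	A	210	229
TM6b	A	233	252
TM7	A	258	281
TM8	A	303	330
TM9	A	340	365
TM10a	A	370	385
TM10b	A	387	405
TM11	A	410	432
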