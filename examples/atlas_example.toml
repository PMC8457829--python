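# Illustrative geometry for scoring the wing-disc morphogens.
#
# Only the decay lengths (and, for Bcd and Dpp, the boundary ranges and
# measured precisions) are printed in the primary literature; the patterned
# lengths and cell sizes below are SYNTHETIC illustrative values of the
# right order for the Drosophila wing imaginal disk, provided so that the
# scoring pipeline can be exercised end to end.  Replace them with
# measured values for any quantitative use.

[morphogens.Bcd]
lcell_um = 10.0
a_um = 10.0
provenance = "example: cell size from L/lcell = 50 on a 500 um embryo"

[morphogens.Wg]
L_um = 30.0
xb_rel = [0.35, 0.45]
lcell_um = 2.5
provenance = "example: illustrative wing-disc geometry (synthetic)"

[morphogens.Hh]
L_um = 45.0
xb_rel = [0.4, 0.5]
lcell_um = 2.5
provenance = "example: illustrative wing-disc geometry (synthetic)"

[morphogens.Dpp]
L_um = 85.0
lcell_um = 2.5
provenance = "example: illustrative wing-disc geometry (synthetic)"
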