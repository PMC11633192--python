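# Endmember zone library for dual-isotope N2O source classification.
#
# Units: per-mil. "sp" is site preference (frame-free); "d15n_bulk" and "d18o"
# are substrate-referenced (product minus substrate) deltas. Each key is a
# closed interval [low, high]; a zone constrains only the axes it lists.
#
# The DN (nitrate-ammonification / DNRA) zone is the range established from
# pure-culture Geobacteraceae incubations and ships as the package's primary
# zone. All OTHER zones below are ILLUSTRATIVE literature-typical ranges
# compiled from published pure-culture surveys of denitrification and
# nitrification isotopocule signatures; they are deliberately user-editable —
# replace them with the compilation your study uses.
#
# Note on the cNor endmember: the narrative SP range for cNor-type NO
# reduction is printed in the source literature as "7.5 per mil to 3.0 per mil"
# (order/sign as printed, apparently inverted), while the point endmember used
# for mixing is -5.9 +/- 2.1 per mil. Recorded verbatim here without
# resolution; the mixing module uses the point endmember.

[zones.DN]
sp = [43.0, 49.9]
d15n_bulk = [-39.9, -5.8]
d18o = [14.1, 30.5]
source = "this package's bundled Geobacteraceae culture survey"

[zones.bD]
sp = [-10.7, 1.6]
d15n_bulk = [-54.0, -10.0]
d18o = [10.0, 45.0]
source = "editable default: bacterial denitrification, literature-typical"

[zones.fD]
sp = [21.9, 39.1]
d15n_bulk = [-50.0, -10.0]
d18o = [30.0, 55.0]
source = "editable default: fungal denitrification, literature-typical"

[zones.NI]
sp = [25.0, 38.7]
d15n_bulk = [-62.0, -45.0]
d18o = [13.0, 35.0]
source = "editable default: nitrification (NH2OH oxidation), literature-typical"

[zones.nD]
sp = [-13.6, 1.9]
d15n_bulk = [-70.0, -35.0]
d18o = [-10.0, 15.0]
source = "editable default: nitrifier denitrification, literature-typical"

[zones.cD]
sp = [15.0, 22.0]
d15n_bulk = [-35.0, -20.0]
d18o = [15.0, 25.0]
source = "editable default: chemical denitrification, literature-typical"
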