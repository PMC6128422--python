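# SYNTHETIC PLACEHOLDER candidate adaptive-SNP list (46 ids).
# The real list of top candidate adaptive SNPs for the Italian population is
# distributed only as unreleased supplementary material; this stand-in keeps
# the candidate-intersection interface exercisable.  The six rsids below are
# the adaptive loci named in the main text; the remaining 40 ids are
# synthetic.
rs2111720
rs1127102
rs3739704
rs1053959
rs3116602
rs3118914
rsSYN00001
rsSYN00002
rsSYN00003
rsSYN00004
rsSYN00005
rsSYN00006
rsSYN00007
rsSYN00008
rsSYN00009
rsSYN00010
rsSYN00011
rsSYN00012
rsSYN00013
rsSYN00014
rsSYN00015
rsSYN00016
rsSYN00017
rsSYN00018
rsSYN00019
rsSYN00020
rsSYN00021
rsSYN00022
rsSYN00023
rsSYN00024
rsSYN00025
rsSYN00026
rsSYN00027
rsSYN00028
rsSYN00029
rsSYN00030
rsSYN00031
rsSYN00032
rsSYN00033
rsSYN00034
rsSYN00035
rsSYN00036
rsSYN00037
rsSYN00038
rsSYN00039
rsSYN00040
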