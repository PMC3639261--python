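snp_id,major,minor,case_hom_major,case_het,case_hom_minor,control_hom_major,control_het,control_hom_minor
rs4981504,G,A,3349,1649,211,3444,1659,204
rs4684243,A,T,2737,2041,418,2827,2113,367
rs6891143,C,T,3464,1561,188,3593,1539,187
rs2269772,G,A,4246,921,39,4375,880,46
rs10860812,G,A,1662,2521,1022,1553,2674,1093
rs893881,T,C,2055,2462,691,2118,2449,730
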