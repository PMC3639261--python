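snp_id,major,minor,case_hom_major,case_het,case_hom_minor,control_hom_major,control_het,control_hom_minor
rs4981504,G,A,1092,734,123,1783,1014,141
rs4684243,A,T,988,787,177,1609,1122,206
rs6891143,C,T,1368,531,48,2186,695,55
rs2269772,G,A,1682,261,8,2438,474,24
rs10860812,G,A,695,908,344,939,1387,602
rs893881,T,C,761,920,242,1000,1446,466
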