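# Example input for `trackrbe rbe-sobp`: measurement positions of a proton
# spread-out Bragg peak with their delivery dose rates and dose-weighted LET.
# e_kin_mev_u values are implementer-derived pairings from standard proton
# stopping-power tables for the listed LET_d, not measured beam energies.
depth_mm,rate_gy_min,let_d_kev_um,e_kin_mev_u,n_fractions
35,11,2.0,27.7,1
100,18,3.0,16.5,1
120,42,4.1,12.6,1
127,53,5.3,8.4,1
35,8,2.0,27.7,2
100,14,3.0,16.5,2
120,31,4.1,12.6,2
127,41,5.3,8.4,2
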