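# Genotype coefficients for the two Malian Guinea-race sorghum cultivars.
# CSM63E: early, weakly photoperiod-sensitive, grown in the Sahelian zone.
# CSM335: medium-duration, photoperiod-sensitive, grown in the Sudanian zone.
# Thermal durations in degCd; photoperiods in h; Ppslope in degCd/h;
# dm_per_seed in g/seed; maxGFRate in mg/grain/degCd; aMaxSlope cm2/leaf,
# aMaxIntercept cm2.  Growth parameters (plastochron onward) take package
# defaults and can be overridden here.
CSM63E:
  Ppcrit1: 11.5
  Ppcrit2: 13.5
  Ppslope: 126.0
  tt_endjuv_to_init_base: 50.0
  tt_flag_to_flower: 170.0
  tt_flower_to_start_grain: 80.0
  tt_flower_to_maturity: 484.0
  tt_maturity_to_ripe: 1.0
  dm_per_seed: 0.00083
  maxGFRate: 0.090
  largest_leaf_multiplier: 0.783
  aMaxSlope: 17.163
  aMaxIntercept: -71.354
CSM335:
  Ppcrit1: 11.5
  Ppcrit2: 13.5
  Ppslope: 226.0
  tt_endjuv_to_init_base: 50.0
  tt_flag_to_flower: 170.0
  tt_flower_to_start_grain: 80.0
  tt_flower_to_maturity: 518.0
  tt_maturity_to_ripe: 1.0
  dm_per_seed: 0.0015
  maxGFRate: 0.045
  largest_leaf_multiplier: 0.698
  aMaxSlope: 32.9
  aMaxIntercept: -296.0
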