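site_id,site_type,lon,lat,measured,predicted
dune_1,mobile_dune,108.26,40.71,5.30,10.26
dune_2,mobile_dune,108.29,40.70,13.97,14.62
dune_3,mobile_dune,108.35,40.70,4.32,1.27
dune_4,mobile_dune,108.29,40.71,10.48,12.65
farm_1,farmland,109.95,40.30,5.87,6.02
farm_2,farmland,109.90,40.31,6.45,6.76
farm_3,farmland,109.82,40.37,5.36,11.31
farm_4,farmland,108.37,40.70,1.54,1.42
farm_5,farmland,108.36,40.70,0.11,0.10
farm_6,farmland,108.41,40.71,0.03,0.28
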