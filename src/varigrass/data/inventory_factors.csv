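input_name,stage,unit,quantity,quantity_basis,gwp_kg_co2e_per_unit,ced_mj_per_unit,aware_m3_per_unit
nitrogen_fertilizer,agriculture,kg,85.72,per_ha_yr,3.6,55.0,283.2
phosphate_fertilizer,agriculture,kg,13.0,per_ha_yr,1.2,15.0,3.0
potash_fertilizer,agriculture,kg,49.0,per_ha_yr,0.65,9.0,1.5
herbicide_atrazine,agriculture,kg,1.1,per_ha_yr,11.0,197.6,20.0
herbicide_quinclorac,agriculture,kg,0.4,per_ha_yr,11.0,197.6,20.0
field_operations_diesel,agriculture,L,25.0,per_ha_yr,3.35,48.0,0.05
grass_seed,agriculture,kg,10.0,per_ha_rotation,1.5,20.0,5.0
seed_transport_161km,agriculture,t*km,1.61,per_ha_rotation,0.1,2.2,0.001
harvest_diesel,logistics,L,5.5,per_Mg,3.2,43.0,0.05
truck_transport,logistics,t*km,65.0,per_Mg,0.1,2.2,0.001
grinding_electricity,logistics,kWh,28.0,per_Mg,0.45,10.8,0.3
sulfuric_acid,biorefinery,kg,22.0,per_Mg_feed,0.13,1.9,8.0
ammonia,biorefinery,kg,11.0,per_Mg_feed,2.65,42.0,40.0
cellulase_enzyme,biorefinery,kg,11.22,per_Mg_feed,5.0,111.4,250.0
glucose_enzyme_feed,biorefinery,kg,25.0,per_Mg_feed,0.75,15.0,200.0
caustic_soda,biorefinery,kg,12.0,per_Mg_feed,1.35,24.0,30.0
makeup_water,biorefinery,m3,5.0,per_Mg_feed,0.0003,0.006,1640.2
chemicals_other,biorefinery,kg,10.0,per_Mg_feed,2.0,30.0,100.0
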