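ncp_id,label,category,applicable_lineages,negative_allowed,sources
potential_crop,Potential crop (genetic resource),material,tracheophyte,true,references;expert
solid_wood,Solid wood,material,tracheophyte,false,references;expert
burned_wood,Burned wood,material,tracheophyte,false,references;expert
wild_food,Wild food,material,tracheophyte;vertebrate,true,references;expert
wild_use,"Wild use (medicinal, dye, fur)",material,tracheophyte;vertebrate,true,references;expert
mellifera,Mellifera use,material,tracheophyte,false,references;expert;analytics
forage_pasture,Forage/pasture,material,tracheophyte,true,references;expert;analytics
iconic_species,Iconic species,non_material,tracheophyte;vertebrate,false,references;analytics
scientific_interest,Scientific research interest,non_material,tracheophyte;vertebrate,false,references;analytics
endangered_habitat,Linked to an endangered habitat,non_material,tracheophyte;vertebrate,false,references;expert
decontamination,Decontamination,regulating,tracheophyte,false,references;expert
riverbank_erosion,Riverbank erosion control,regulating,tracheophyte;vertebrate,true,references;expert
hedge_crop_yield,Hedge for crop yield,regulating,tracheophyte,false,references;expert;analytics
reduce_species_damage,Reduction of species damage and disease vector species,regulating,vertebrate,true,references;expert
reduce_runoff,Reduce runoff from agroecosystems,regulating,tracheophyte,true,references;expert;analytics
keystone_species,Keystone species,regulating,tracheophyte;vertebrate,true,references;expert
reduce_landslide,Reduce landslide,regulating,tracheophyte;vertebrate,true,references;expert
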