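object_type,source
Cotton Buds,Sewage
Menstrual Hygiene Products,Sewage
Menstrual Hygiene Packaging,Sewage
Wet Wipes,Sewage
Buoys,FishingAquaculture
Netfloats,FishingAquaculture
Cage Nets,FishingAquaculture
Jerrycans,FishingAquaculture
Nets,FishingAquaculture
Ropes,FishingAquaculture
Sandals,HouseholdLeisure
Cosmetics Container,HouseholdLeisure
Shoes,HouseholdLeisure
Shoe Soles,HouseholdLeisure
Cigarette Stubs,HouseholdLeisure
Lighters,HouseholdLeisure
Paper And Carton,HouseholdLeisure
Textiles,HouseholdLeisure
Drinking Straws,HouseholdLeisure
Fragments,NotAttributable
Unknown Objects,NotAttributable
Boxes,NotAttributable
Bottles,NotAttributable
Buckets,NotAttributable
Lids,NotAttributable
Beverage Crates,NotAttributable
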