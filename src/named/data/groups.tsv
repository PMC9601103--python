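feature_name	benefit_group
Ammonification Hydrolases	hosts_benefit
Nitrogen Fixation (nifH+nifD)	hosts_benefit
Compatible Solutes	microbes_benefit
Carboxylic Acids	microbes_benefit
Carbohydrate Pentoses	microbes_benefit
General Carbohydrates	microbes_benefit
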