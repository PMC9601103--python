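suite_name	pattern
# Ammonification hydrolases: C-N bond cleaving enzyme families that
# liberate ammonium (oxidoreductases acting on amino groups, hydrolases
# acting on non-peptide C-N bonds including ureases, ammonia-lyases).
Ammonification Hydrolases	EC:1.4.*
Ammonification Hydrolases	EC:3.5.*
Ammonification Hydrolases	EC:4.3.1.*
# Dissolved-organic-matter transporter suites. SYNTHETIC PLACEHOLDER
# membership: representative KO transporter families standing in for the
# curated DOM transporter list; replace with a user-supplied suites file
# for real analyses.
Compatible Solutes	K02000
Compatible Solutes	K02001
Compatible Solutes	K02002
Compatible Solutes	K05845
Compatible Solutes	K05846
Carboxylic Acids	K13788
Carboxylic Acids	K01895
Carboxylic Acids	K14393
Carboxylic Acids	K11264
Carbohydrate Pentoses	K10543
Carbohydrate Pentoses	K10544
Carbohydrate Pentoses	K10545
General Carbohydrates	K10108
General Carbohydrates	K10109
General Carbohydrates	K10110
General Carbohydrates	K17315
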