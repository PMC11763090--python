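product_name	substances	substance_class	route	registration	concentration	package_amount
amoxicillin	amoxicillin	aminopenicillin	unknown	veterinary
ampicillin	ampicillin	aminopenicillin	unknown	veterinary
benzylpenicillin	benzylpenicillin	aminopenicillin	unknown	veterinary
penicillin	benzylpenicillin	aminopenicillin	unknown	veterinary
amoxicillin/clavulansaeure	amoxicillin/clavulanic acid	aminopenicillin+inhibitor	unknown	veterinary
amoxicillin-clavulanic acid	amoxicillin/clavulanic acid	aminopenicillin+inhibitor	unknown	veterinary
amoxi-tabs 250 mg	amoxicillin	aminopenicillin	oral	veterinary	250 mg	100
duphamox la	amoxicillin	aminopenicillin	parenteral	veterinary	150 mg/ml	100 ml
synulox 250 mg tabletten	amoxicillin/clavulanic acid	aminopenicillin+inhibitor	oral	veterinary	250 mg	100
synulox rtu	amoxicillin/clavulanic acid	aminopenicillin+inhibitor	parenteral	veterinary	175 mg/ml	100 ml
clavaseptin 250 mg	amoxicillin/clavulanic acid	aminopenicillin+inhibitor	oral	veterinary	250 mg	100
enrofloxacin	enrofloxacin	fluoroquinolone	unknown	veterinary
baytril 50 mg tabletten	enrofloxacin	fluoroquinolone	oral	veterinary	50 mg	100
baytril 2,5% injektionsloesung	enrofloxacin	fluoroquinolone	parenteral	veterinary	25 mg/ml	100 ml
marbofloxacin	marbofloxacin	fluoroquinolone	unknown	veterinary
marbocyl 20 mg	marbofloxacin	fluoroquinolone	oral	veterinary	20 mg	100
pradofloxacin	pradofloxacin	fluoroquinolone	unknown	veterinary
veraflox 60 mg	pradofloxacin	fluoroquinolone	oral	veterinary	60 mg	7
ofloxacin	ofloxacin	fluoroquinolone	unknown	human
floxal augentropfen	ofloxacin	fluoroquinolone	local	human	3 mg/ml	5 ml
cefalexin	cefalexin	cephalosporin-1/2-gen	unknown	veterinary
rilexine 300 mg	cefalexin	cephalosporin-1/2-gen	oral	veterinary	300 mg	140
cefazolin	cefazolin	cephalosporin-1/2-gen	parenteral	human
cefovecin	cefovecin	cephalosporin-3/4-gen	parenteral	veterinary
convenia 80 mg/ml	cefovecin	cephalosporin-3/4-gen	parenteral	veterinary	80 mg/ml	10 ml
ceftiofur	ceftiofur	cephalosporin-3/4-gen	parenteral	veterinary
erythromycin	erythromycin	macrolide	unknown	human
azithromycin	azithromycin	macrolide	oral	human
tylosin	tylosin	macrolide	parenteral	veterinary
polymyxin	polymyxin b	polymyxin	unknown	veterinary
polymyxin b	polymyxin b	polymyxin	unknown	veterinary
colistin	colistin	polymyxin	unknown	veterinary
surolan ohrentropfen	polymyxin b	polymyxin	local	veterinary	0.5293 mg/ml	15 ml
gentamicin	gentamicin	aminoglycoside	unknown	veterinary
gentamicin eye drops	gentamicin	aminoglycoside	local	human	5 mg/ml	5 ml
gentamytrex augentropfen	gentamicin	aminoglycoside	local	human	5 mg/ml	5 ml
neomycin	neomycin	aminoglycoside	unknown	veterinary
neomycin-salbe	neomycin	aminoglycoside	local	veterinary	5 mg/g	30 g
oxytetracycline	oxytetracycline	tetracycline	unknown	veterinary
oxytetracyclin augensalbe	oxytetracycline	tetracycline	local	human	10 mg/g	5 g
doxycycline	doxycycline	tetracycline	oral	veterinary
ronaxan 100 mg	doxycycline	tetracycline	oral	veterinary	100 mg	10
metronidazole	metronidazole	nitroimidazole	unknown	veterinary
metrobactin 250 mg	metronidazole	nitroimidazole	oral	veterinary	250 mg	100
trimethoprim/sulfadiazin	trimethoprim/sulfadiazine	other	oral	veterinary
clindamycin	clindamycin	other	oral	veterinary
meloxicam		non-antibiotic	oral	veterinary
metacam 1,5 mg/ml	 	non-antibiotic	oral	veterinary	1.5 mg/ml	32 ml
rimadyl 50 mg		non-antibiotic	oral	veterinary	50 mg	100
vetmedin 5 mg		non-antibiotic	oral	veterinary	5 mg	100
carprofen		non-antibiotic	oral	veterinary
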