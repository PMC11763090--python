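breed_name	mean_weight_kg	short_nose	skin_predisposed	entropion_predisposed
Affenpinscher	4.0	1	0	0
Boston Terrier	8.0	1	0	0
Bordeauxdogge	55.0	1	0	0
Boxer	30.0	1	0	0
Cavalier King Charles Spaniel	8.0	1	0	0
Chihuahua	2.5	1	0	0
Englische Bulldogge	24.0	1	1	1
Franzoesische Bulldogge	11.0	1	1	0
Griffon	4.5	1	0	0
Lhasa Apso	7.0	1	0	0
Mops	8.0	1	1	0
Norwich Terrier	5.5	1	0	0
Pekinese	4.5	1	1	0
Shih Tzu	6.0	1	0	0
Toy Spaniel	4.0	1	0	0
Yorkshire Terrier	3.0	1	1	0
Zwergspitz	2.5	1	0	0
American Staffordshire Terrier	27.0	0	1	0
Dackel	9.0	0	1	0
Dobermann	40.0	0	1	0
Deutsche Dogge	60.0	0	1	0
Labrador Retriever	31.5	0	1	0
Greyhound	30.0	0	1	0
Irish Setter	29.0	0	1	0
Pudel	20.0	0	1	1
Basset Hound	25.0	0	1	1
Bloodhound	45.0	0	1	1
Bulldogge	24.0	0	1	1
Bullmastiff	55.0	0	1	0
Mastino Napoletano	65.0	0	1	0
Shar Pei	22.0	0	1	1
Berner Sennenhund	45.0	0	0	1
Bernhardiner	75.0	0	0	1
Cocker Spaniel	13.0	0	0	1
Neufundlaender	60.0	0	0	1
Bull Terrier	27.0	0	0	1
Chow-Chow	25.0	0	0	1
Rottweiler	45.0	0	0	1
Deutscher Schaeferhund	32.0	0	0	0
Golden Retriever	32.0	0	0	0
Jack Russell Terrier	6.0	0	0	0
Beagle	12.0	0	0	0
Border Collie	17.0	0	0	0
Malteser	3.5	0	0	0
Havaneser	5.0	0	0	0
Australian Shepherd	25.0	0	0	0
Magyar Vizsla	25.0	0	0	0
Weimaraner	32.0	0	0	0
Dalmatiner	27.0	0	0	0
Kleiner Muensterlaender	20.0	0	0	0
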