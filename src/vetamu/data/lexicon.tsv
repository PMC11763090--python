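keyword	category
impfung	diagnostics/therapy
impfen	diagnostics/therapy
vakzination	diagnostics/therapy
kastration	diagnostics/therapy
kastrieren	diagnostics/therapy
sterilisation	diagnostics/therapy
euthanasie	diagnostics/therapy
einschlaefern	diagnostics/therapy
untersuchung	diagnostics/therapy
allgemeinuntersuchung	diagnostics/therapy
kontrolle	diagnostics/therapy
nachkontrolle	diagnostics/therapy
behandlung	diagnostics/therapy
prophylaxe	diagnostics/therapy
blutabnahme	diagnostics/therapy
blutbild	diagnostics/therapy
labor	diagnostics/therapy
roentgen	diagnostics/therapy
operation	diagnostics/therapy
vaccination	diagnostics/therapy
haut	dermatology
dermatitis	dermatology
pyodermie	dermatology
juckreiz	dermatology
pruritus	dermatology
ekzem	dermatology
hotspot	dermatology
hot spot	dermatology
alopezie	dermatology
haarausfall	dermatology
abszess	dermatology
pusteln	dermatology
atopie	dermatology
raeude	dermatology
milben	dermatology
schuppen	dermatology
leckdermatitis	dermatology
lahmheit	orthopedics
lahmt	orthopedics
arthrose	orthopedics
arthritis	orthopedics
kreuzband	orthopedics
kreuzbandriss	orthopedics
hueftdysplasie	orthopedics
patellaluxation	orthopedics
gelenk	orthopedics
gelenkschmerz	orthopedics
spondylose	orthopedics
bewegungsapparat	orthopedics
durchfall	digestive system
diarrhoe	digestive system
erbrechen	digestive system
vomitus	digestive system
gastritis	digestive system
enteritis	digestive system
gastroenteritis	digestive system
magen	digestive system
darm	digestive system
kolik	digestive system
obstipation	digestive system
verstopfung	digestive system
pankreatitis	digestive system
giardien	digestive system
husten	respiratory system
atemnot	respiratory system
dyspnoe	respiratory system
bronchitis	respiratory system
pneumonie	respiratory system
lungenentzuendung	respiratory system
niesen	respiratory system
nasenausfluss	respiratory system
katzenschnupfen	respiratory system
tracheitis	respiratory system
lunge	respiratory system
otitis	otology
otitis externa	otology
otitis media	otology
ohr	otology
ohren	otology
ohrenentzuendung	otology
ohrmilben	otology
othaematom	otology
gehoergang	otology
ohrenreinigung	otology
auge	ophthalmology
augen	ophthalmology
konjunktivitis	ophthalmology
bindehautentzuendung	ophthalmology
hornhaut	ophthalmology
hornhautulkus	ophthalmology
keratitis	ophthalmology
entropium	ophthalmology
ektropium	ophthalmology
augenausfluss	ophthalmology
uveitis	ophthalmology
zystitis	urogenital tract
blasenentzuendung	urogenital tract
blase	urogenital tract
harnwegsinfekt	urogenital tract
niere	urogenital tract
niereninsuffizienz	urogenital tract
pyometra	urogenital tract
prostata	urogenital tract
harnabsatz	urogenital tract
urin	urogenital tract
gebaermutter	urogenital tract
notfall	emergency
kollaps	emergency
schock	emergency
magendrehung	emergency
reanimation	emergency
trauma	trauma
unfall	trauma
autounfall	trauma
bissverletzung	trauma
bisswunde	trauma
wunde	trauma
verletzung	trauma
fraktur	trauma
prellung	trauma
schnittwunde	trauma
vergiftung	intoxication
intoxikation	intoxication
giftkoeder	intoxication
rattengift	intoxication
giftaufnahme	intoxication
diabetes	endocrinology
schilddruese	endocrinology
hyperthyreose	endocrinology
hypothyreose	endocrinology
cushing	endocrinology
addison	endocrinology
insulin	endocrinology
entwurmung	routine
wurmkur	routine
floehe	routine
zecken	routine
parasiten	routine
chippen	routine
mikrochip	routine
medikamentenabgabe	routine
krallenschneiden	routine
futterberatung	routine
fieber	systemic
schwaeche	systemic
apathie	systemic
anorexie	systemic
inappetenz	systemic
gewichtsverlust	systemic
abgeschlagen	systemic
exsikkose	systemic
dehydratation	systemic
ultraschall	unclear
oedem	unclear
schwellung	unclear
befund	unclear
auffaellig	unclear
herz	cardiology
herzgeraeusch	cardiology
kardiomyopathie	cardiology
herzinsuffizienz	cardiology
mitralklappe	cardiology
epilepsie	neurology
krampfanfall	neurology
ataxie	neurology
laehmung	neurology
bandscheibenvorfall	neurology
zahnstein	dentistry
zahn	dentistry
zaehne	dentistry
gingivitis	dentistry
zahnextraktion	dentistry
parodontitis	dentistry
maulhoehle	dentistry
tumor	oncology
neoplasie	oncology
mastzelltumor	oncology
lymphom	oncology
metastase	oncology
karzinom	oncology
parvovirose	infectious disease
leptospirose	infectious disease
borreliose	infectious disease
fiv	infectious disease
felv	infectious disease
leukose	infectious disease
panleukopenie	infectious disease
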