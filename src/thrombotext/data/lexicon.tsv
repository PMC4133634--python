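# Demonstration concept lexicon: term <TAB> concept_type <TAB> provenance
# Types: Anatomy, ThromboPat, Exam, K (clinically relevant finding), PP (post-partum)
artère pulmonaire droite	Anatomy	core
artère pulmonaire gauche	Anatomy	core
artères pulmonaires	Anatomy	core
tronc de l'artère pulmonaire	Anatomy	core
artère lobaire inférieure droite	Anatomy	core
artère lobaire supérieure gauche	Anatomy	core
artère segmentaire	Anatomy	core
lobe supérieur droit	Anatomy	core
lobe supérieur gauche	Anatomy	core
lobe inférieur droit	Anatomy	core
lobe inférieur gauche	Anatomy	core
lobe moyen	Anatomy	core
veine fémorale commune	Anatomy	core
veine fémorale superficielle	Anatomy	core
veine poplitée droite	Anatomy	clinical
veine poplitée gauche	Anatomy	clinical
veine iliaque externe	Anatomy	core
veines surales	Anatomy	clinical
veine cave inférieure	Anatomy	core
foie	Anatomy	core
rein droit	Anatomy	core
rein gauche	Anatomy	core
surrénale droite	Anatomy	core
surrénale gauche	Anatomy	core
thyroïde	Anatomy	core
médiastin	Anatomy	core
pancréas	Anatomy	core
rate	Anatomy	core
embolie pulmonaire	ThromboPat	core
embolie pulmonaire bilatérale	ThromboPat	clinical
embolie	ThromboPat	core
EP	ThromboPat	clinical
thrombose veineuse profonde	ThromboPat	core
thrombose veineuse	ThromboPat	core
thrombose	ThromboPat	core
TVP	ThromboPat	clinical
thrombus	ThromboPat	clinical
défect endoluminal	ThromboPat	clinical
nodule	K	finding
nodule pulmonaire	K	finding
micronodule	K	finding
masse	K	finding
masse suspecte	K	finding
adénopathie	K	finding
adénopathies	K	finding
kyste	K	finding
lésion nodulaire	K	finding
angioscanner thoracique	Exam	clinical
angioscanner du thorax	Exam	clinical
angioscanner	Exam	clinical
phléboscan	Exam	clinical
phlebo-scan	Exam	clinical
scanner thoracique	Exam	clinical
phlébographie	Exam	core
post-partum	PP	clinical
accouchement	PP	clinical
césarienne	PP	clinical
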