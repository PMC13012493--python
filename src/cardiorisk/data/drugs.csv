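name,therapeutic_class,qt,torsades,ss,diuretic,cv_caution
methadone,opioid_analgesic,true,true,true,false,false
tramadol,opioid_analgesic,true,true,true,false,false
morphine,opioid_analgesic,false,false,false,false,false
fentanyl,opioid_analgesic,false,false,false,false,true
hydromorphone,opioid_analgesic,false,false,false,false,false
haloperidol,antipsychotic,true,false,false,false,false
risperidone,antipsychotic,true,false,false,false,false
levomepromazine,antipsychotic,true,false,false,false,false
nortriptyline,tricyclic_antidepressant,true,false,false,false,false
amitriptyline,tricyclic_antidepressant,true,false,false,false,false
promethazine,antihistamine,true,false,false,false,false
ondansetron,antiemetic,true,false,false,false,false
domperidone,antiemetic,true,false,false,false,false
metoclopramide,antiemetic,false,false,false,false,false
chloroquine,antimalarial,true,false,false,false,false
hydroxychloroquine,antimalarial,true,false,false,false,false
lopinavir,anti_hiv_antiviral,true,false,false,false,false
ritonavir,anti_hiv_antiviral,true,false,false,false,false
cyclobenzaprine,muscle_relaxant,true,false,false,false,false
propofol,sedative,false,false,false,false,false
midazolam,sedative,false,false,false,false,false
dexmedetomidine,sedative,false,false,false,false,true
ketamine,sedative,false,false,false,false,false
azithromycin,antibiotic,true,false,false,false,false
moxifloxacin,antibiotic,true,false,false,false,false
furosemide,diuretic,false,false,false,true,false
propranolol,other,true,false,false,false,false
clonidine,other,true,false,false,false,false
amiodarone,other,true,false,false,false,false
sertraline,other,true,false,false,false,false
escitalopram,other,true,false,false,false,false
tacrolimus,other,true,false,false,false,false
paracetamol,other,false,false,false,false,false
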