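# Hypothetical-intervention rule set: six therapeutic-class substitutions or
# withdrawals that remove QT-prolonging exposure from an ICU prescription.
# replacement_candidates are ordered; the default policy picks the first.
- rule_id: i
  action: replace
  source_drugs: [methadone, tramadol]
  replacement_candidates: [morphine, fentanyl, hydromorphone]
- rule_id: ii
  action: replace
  source_drugs: [nortriptyline, haloperidol, promethazine]
  replacement_candidates: [propofol, midazolam, dexmedetomidine, ketamine]
- rule_id: iii
  action: replace
  source_drugs: [ondansetron, domperidone]
  replacement_candidates: [metoclopramide]
- rule_id: iv
  action: withdraw
  source_drugs: [chloroquine, hydroxychloroquine]
  replacement_candidates: []
- rule_id: v
  action: withdraw
  source_drugs: [lopinavir, ritonavir]
  replacement_candidates: []
- rule_id: vi
  action: withdraw
  source_drugs: [cyclobenzaprine]
  replacement_candidates: []
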