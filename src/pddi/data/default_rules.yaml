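# Default rule set for the analgesic pDDI screen: the drug-class rosters and
# the nine interaction rules used in the 2018 Polish national dispensation
# analysis. Codes are ATC (WHO Anatomical Therapeutic Chemical) identifiers.
#
# Schema:
#   catalog: list of {code, name, class, aliases?}
#   rules:   list of {rule_id, display_name, side_a: [classes...],
#                     side_b: [classes...], category (C|D|X),
#                     min_daily_dose_mg?, require_distinct_substance?}
catalog:
  # NSAIDs
  - {code: M01AB05, name: diclofenac, class: NSAID}
  - {code: M01AE01, name: ibuprofen, class: NSAID}
  - {code: M01AH01, name: celecoxib, class: NSAID}
  - {code: M01AE02, name: naproxen, class: NSAID}
  - {code: M01AH05, name: etoricoxib, class: NSAID}
  - {code: M01AC01, name: piroxicam, class: NSAID}
  - {code: M01AC06, name: meloxicam, class: NSAID}
  - {code: M01AE03, name: ketoprofen, class: NSAID}
  - {code: M01AE17, name: dexketoprofen, class: NSAID}
  - {code: M01AB16, name: aceclofenac, class: NSAID}
  - {code: M01AC05, name: lornoxicam, class: NSAID}
  - {code: M01AA01, name: phenylbutazone, class: NSAID}
  - {code: M01AG01, name: mefenamic acid, class: NSAID}
  - {code: M01AX17, name: nimesulide, class: NSAID}
  # Tramadol: a weak (WHO step-2) opioid, screened as its own class with a
  # daily-dose condition, separately from the strong opioids.
  - {code: N02AX02, name: tramadol, class: TRAMADOL}
  # Opioids (codeine is grouped here: in Poland it is prescribed under the
  # same special "narcotic" prescription regime as strong opioids)
  - {code: R05DA04, name: codeine, class: OPIOID}
  - {code: N02AA08, name: dihydrocodeine, class: OPIOID}
  - {code: N02AA01, name: morphine, class: OPIOID}
  - {code: N02AA05, name: oxycodone, class: OPIOID}
  - {code: N02AE01, name: buprenorphine, class: OPIOID}
  - {code: N02AB03, name: fentanyl, class: OPIOID}
  # Benzodiazepines
  - {code: N05BA12, name: alprazolam, class: BENZODIAZEPINE}
  - {code: N05BA01, name: diazepam, class: BENZODIAZEPINE}
  - {code: N05BA06, name: lorazepam, class: BENZODIAZEPINE}
  - {code: N05CD07, name: temazepam, class: BENZODIAZEPINE}
  - {code: N05BA08, name: bromazepam, class: BENZODIAZEPINE}
  # Gabapentinoids
  - {code: N03AX12, name: gabapentin, class: GABAPENTINOID}
  - {code: N03AX16, name: pregabalin, class: GABAPENTINOID}
  # Oral glucocorticoids
  - {code: H02AB07, name: prednisone, class: GC}
  - {code: H02AB06, name: prednisolone, class: GC}
  - {code: H02AB04, name: methylprednisolone, class: GC}
  # Antiplatelet drugs
  - {code: B01AC05, name: ticlopidine, class: ANTIPLATELET}
  - {code: B01AC04, name: clopidogrel, class: ANTIPLATELET}
  - {code: B01AC24, name: ticagrelor, class: ANTIPLATELET}
  - {code: B01AC22, name: prasugrel, class: ANTIPLATELET}
  # Antihypertensives: ARBs, ACEIs and beta-blockers only (the classes whose
  # blood-pressure effect NSAIDs antagonise; calcium-channel blockers are
  # deliberately absent)
  - {code: C09CA03, name: valsartan, class: ANTIHYPERTENSIVE_ARB}
  - {code: C09CA01, name: losartan, class: ANTIHYPERTENSIVE_ARB}
  - {code: C09CA07, name: telmisartan, class: ANTIHYPERTENSIVE_ARB}
  - {code: C09CA04, name: irbesartan, class: ANTIHYPERTENSIVE_ARB}
  - {code: C09CA06, name: candesartan, class: ANTIHYPERTENSIVE_ARB}
  - {code: C09AA02, name: enalapril, class: ANTIHYPERTENSIVE_ACEI}
  - {code: C09AA05, name: ramipril, class: ANTIHYPERTENSIVE_ACEI}
  - {code: C09AA06, name: quinapril, class: ANTIHYPERTENSIVE_ACEI}
  - {code: C09AA04, name: perindopril, class: ANTIHYPERTENSIVE_ACEI}
  - {code: C09AA15, name: zofenopril, class: ANTIHYPERTENSIVE_ACEI}
  - {code: C07AB02, name: metoprolol, class: ANTIHYPERTENSIVE_BB}
  # "nebiolol" kept as an alias: the source roster circulates with that
  # spelling for nebivolol
  - {code: C07AB12, name: nebivolol, class: ANTIHYPERTENSIVE_BB, aliases: [nebiolol]}
  - {code: C07AG02, name: carvedilol, class: ANTIHYPERTENSIVE_BB}
  - {code: C07AA05, name: propranolol, class: ANTIHYPERTENSIVE_BB}
  - {code: C07AB05, name: betaxolol, class: ANTIHYPERTENSIVE_BB}
  # SSRIs
  - {code: N06AB05, name: paroxetine, class: SSRI}
  - {code: N06AB03, name: fluoxetine, class: SSRI}
  - {code: N06AB04, name: citalopram, class: SSRI}
  - {code: N06AB10, name: escitalopram, class: SSRI}
  # SNRIs
  - {code: N06AX21, name: duloxetine, class: SNRI}
  - {code: N06AX16, name: venlafaxine, class: SNRI}
  # Oral anticoagulants
  - {code: B01AA03, name: warfarin, class: OAC}
  - {code: B01AA07, name: acenocoumarol, class: OAC}

rules:
  - rule_id: nsaid_antihypertensive
    display_name: NSAIDs + Antihypertensive drugs
    side_a: [NSAID]
    side_b: [ANTIHYPERTENSIVE_ACEI, ANTIHYPERTENSIVE_ARB, ANTIHYPERTENSIVE_BB]
    category: C
  - rule_id: nsaid_nsaid
    display_name: NSAIDs + NSAIDs
    side_a: [NSAID]
    side_b: [NSAID]
    category: D
    require_distinct_substance: true
  - rule_id: nsaid_gc
    display_name: NSAIDs + GCs
    side_a: [NSAID]
    side_b: [GC]
    category: C
  - rule_id: nsaid_ssri_snri
    display_name: NSAIDs + SSRIs/SNRIs
    side_a: [NSAID]
    side_b: [SSRI, SNRI]
    category: C
  - rule_id: nsaid_oac
    display_name: NSAIDs + OACs
    side_a: [NSAID]
    side_b: [OAC]
    category: C
  - rule_id: nsaid_antiplatelet
    display_name: NSAIDs + Antiplatelet drugs
    side_a: [NSAID]
    side_b: [ANTIPLATELET]
    category: C
  - rule_id: opioid_gabapentinoid
    display_name: Opioids + Gabapentinoids
    side_a: [OPIOID]
    side_b: [GABAPENTINOID]
    category: C
  - rule_id: opioid_benzodiazepine
    display_name: Opioids + Benzodiazepines
    side_a: [OPIOID]
    side_b: [BENZODIAZEPINE]
    category: C
  - rule_id: tramadol_ssri_snri
    display_name: Tramadol + SSRIs/SNRIs
    side_a: [TRAMADOL]
    side_b: [SSRI, SNRI]
    category: C
    min_daily_dose_mg: 200
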