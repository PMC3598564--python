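# Medication-based comorbidity lookup in the style of the RxRisk model:
# a claim for any listed drug in the lookback window flags the category.
# This is a deliberately small, documented simplification covering the twelve
# categories used as adjustment covariates; it is not the full published
# RxRisk classifier.
categories:
  anxiety_tension:
    display_name: "Anxiety & Tension"
    drugs: [alprazolam, lorazepam, oxazepam, temazepam, triazolam, midazolam, buspirone]
  asthma:
    display_name: "Asthma"
    drugs: [albuterol, montelukast, theophylline, fluticasone_salmeterol]
  cardiac_disease:
    display_name: "Cardiac Disease"
    drugs: [amiodarone, sotalol, digoxin]
  coronary_peripheral_vascular:
    display_name: "Coronary/Peripheral Vascular disease"
    drugs: [warfarin, clopidogrel, nitroglycerin, isosorbide_mononitrate, isosorbide_dinitrate]
  depression:
    display_name: "Depression"
    drugs: [sertraline, fluoxetine, citalopram, bupropion]
  diabetes:
    display_name: "Diabetes"
    drugs: [metformin, glipizide, insulin_glargine]
  epilepsy:
    display_name: "Epilepsy"
    drugs: [carbamazepine, phenytoin, levetiracetam]
  end_stage_renal_disease:
    display_name: "End stage renal disease"
    drugs: [sevelamer, calcitriol, epoetin_alfa]
  glaucoma:
    display_name: "Glaucoma"
    drugs: [latanoprost, timolol_ophthalmic]
  heart_disease_hypertension:
    display_name: "Heart Disease/Hypertension"
    drugs: [lisinopril, amlodipine, metoprolol, hydrochlorothiazide]
  hyperlipidemia:
    display_name: "Hyperlipidemia"
    drugs: [atorvastatin, fluvastatin, lovastatin, pravastatin, rosuvastatin, simvastatin,
            fenofibrate, gemfibrozil, ezetimibe, niacin_er]
  irritable_bowel_syndrome:
    display_name: "Irritable Bowel Syndrome"
    drugs: [dicyclomine, hyoscyamine]
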