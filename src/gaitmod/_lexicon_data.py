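"""Built-in reduced lexicons.

A scaled-down drug-name index: 22 drug classes that dominate chronic
polypharmacy in older adults, each with a handful of generic names and
common brand synonyms, plus 12 comorbidity descriptions with English and
German phrasings.  Real deployments would swap in a full ATC-derived
index via :func:`gaitmod.annotation.Lexicon.from_csv`.
"""

# (term, code, kind) — kind in {"drug-generic", "drug-brand"}
DRUG_ENTRIES = [
    # statins
    ("atorvastatin", "statin", "drug-generic"),
    ("simvastatin", "statin", "drug-generic"),
    ("rosuvastatin", "statin", "drug-generic"),
    ("pravastatin", "statin", "drug-generic"),
    ("fluvastatin", "statin", "drug-generic"),
    ("lipitor", "statin", "drug-brand"),
    ("sortis", "statin", "drug-brand"),
    ("zocor", "statin", "drug-brand"),
    ("crestor", "statin", "drug-brand"),
    # 5-alpha-reductase inhibitors
    ("finasteride", "five_alpha_reductase_inhibitor", "drug-generic"),
    ("dutasteride", "five_alpha_reductase_inhibitor", "drug-generic"),
    ("proscar", "five_alpha_reductase_inhibitor", "drug-brand"),
    ("avodart", "five_alpha_reductase_inhibitor", "drug-brand"),
    # ACE inhibitors
    ("lisinopril", "acei", "drug-generic"),
    ("enalapril", "acei", "drug-generic"),
    ("ramipril", "acei", "drug-generic"),
    ("perindopril", "acei", "drug-generic"),
    ("zestril", "acei", "drug-brand"),
    ("triatec", "acei", "drug-brand"),
    ("coversum", "acei", "drug-brand"),
    # aldosterone antagonists / potassium-sparing
    ("spironolactone", "potassium_sparing_diuretic", "drug-generic"),
    ("eplerenone", "potassium_sparing_diuretic", "drug-generic"),
    ("amiloride", "potassium_sparing_diuretic", "drug-generic"),
    ("aldactone", "potassium_sparing_diuretic", "drug-brand"),
    # alpha-adrenergic antagonists
    ("tamsulosin", "alpha_adrenergic_antagonist", "drug-generic"),
    ("doxazosin", "alpha_adrenergic_antagonist", "drug-generic"),
    ("alfuzosin", "alpha_adrenergic_antagonist", "drug-generic"),
    ("pradif", "alpha_adrenergic_antagonist", "drug-brand"),
    # antipsychotics
    ("quetiapine", "antipsychotic", "drug-generic"),
    ("risperidone", "antipsychotic", "drug-generic"),
    ("haloperidol", "antipsychotic", "drug-generic"),
    ("olanzapine", "antipsychotic", "drug-generic"),
    ("seroquel", "antipsychotic", "drug-brand"),
    ("haldol", "antipsychotic", "drug-brand"),
    # aspirin
    ("aspirin", "aspirin", "drug-generic"),
    ("acetylsalicylic", "aspirin", "drug-generic"),
    ("cardiaspirine", "aspirin", "drug-brand"),
    ("aspegic", "aspirin", "drug-brand"),
    # benzodiazepines
    ("lorazepam", "benzodiazepine", "drug-generic"),
    ("oxazepam", "benzodiazepine", "drug-generic"),
    ("diazepam", "benzodiazepine", "drug-generic"),
    ("temesta", "benzodiazepine", "drug-brand"),
    ("seresta", "benzodiazepine", "drug-brand"),
    ("valium", "benzodiazepine", "drug-brand"),
    # beta-blockers
    ("metoprolol", "beta_blocker", "drug-generic"),
    ("bisoprolol", "beta_blocker", "drug-generic"),
    ("nebivolol", "beta_blocker", "drug-generic"),
    ("atenolol", "beta_blocker", "drug-generic"),
    ("beloc", "beta_blocker", "drug-brand"),
    ("concor", "beta_blocker", "drug-brand"),
    # biguanides
    ("metformin", "biguanide", "drug-generic"),
    ("glucophage", "biguanide", "drug-brand"),
    # dihydropyridines
    ("amlodipine", "dihydropyridine", "drug-generic"),
    ("nifedipine", "dihydropyridine", "drug-generic"),
    ("lercanidipine", "dihydropyridine", "drug-generic"),
    ("norvasc", "dihydropyridine", "drug-brand"),
    ("adalat", "dihydropyridine", "drug-brand"),
    # insulins
    ("insulin", "insulin", "drug-generic"),
    ("glargine", "insulin", "drug-generic"),
    ("lantus", "insulin", "drug-brand"),
    ("levemir", "insulin", "drug-brand"),
    # opioids
    ("tramadol", "opioid", "drug-generic"),
    ("oxycodone", "opioid", "drug-generic"),
    ("fentanyl", "opioid", "drug-generic"),
    ("morphine", "opioid", "drug-generic"),
    ("oxycontin", "opioid", "drug-brand"),
    ("durogesic", "opioid", "drug-brand"),
    # proton-pump inhibitors
    ("pantoprazole", "ppi", "drug-generic"),
    ("omeprazole", "ppi", "drug-generic"),
    ("esomeprazole", "ppi", "drug-generic"),
    ("nexium", "ppi", "drug-brand"),
    ("pantozol", "ppi", "drug-brand"),
    # sartans
    ("losartan", "sartan", "drug-generic"),
    ("valsartan", "sartan", "drug-generic"),
    ("candesartan", "sartan", "drug-generic"),
    ("irbesartan", "sartan", "drug-generic"),
    ("diovan", "sartan", "drug-brand"),
    ("atacand", "sartan", "drug-brand"),
    # SSRIs
    ("citalopram", "ssri", "drug-generic"),
    ("escitalopram", "ssri", "drug-generic"),
    ("sertraline", "ssri", "drug-generic"),
    ("paroxetine", "ssri", "drug-generic"),
    ("cipralex", "ssri", "drug-brand"),
    ("zoloft", "ssri", "drug-brand"),
    # sulphonamide loop diuretics
    ("furosemide", "loop_diuretic", "drug-generic"),
    ("torasemide", "loop_diuretic", "drug-generic"),
    ("lasix", "loop_diuretic", "drug-brand"),
    ("torem", "loop_diuretic", "drug-brand"),
    # sulphonamide thiazide-likes
    ("hydrochlorothiazide", "thiazide", "drug-generic"),
    ("indapamide", "thiazide", "drug-generic"),
    ("chlorthalidone", "thiazide", "drug-generic"),
    ("esidrex", "thiazide", "drug-brand"),
    # sulphonylureas
    ("gliclazide", "sulphonylurea", "drug-generic"),
    ("glimepiride", "sulphonylurea", "drug-generic"),
    ("glibenclamide", "sulphonylurea", "drug-generic"),
    ("diamicron", "sulphonylurea", "drug-brand"),
    ("amaryl", "sulphonylurea", "drug-brand"),
    # tricyclic antidepressants
    ("amitriptyline", "tricyclic_antidepressant", "drug-generic"),
    ("nortriptyline", "tricyclic_antidepressant", "drug-generic"),
    ("trimipramine", "tricyclic_antidepressant", "drug-generic"),
    ("saroten", "tricyclic_antidepressant", "drug-brand"),
    # thyroid hormones
    ("levothyroxine", "thyroid_hormone", "drug-generic"),
    ("liothyronine", "thyroid_hormone", "drug-generic"),
    ("euthyrox", "thyroid_hormone", "drug-brand"),
    ("eltroxin", "thyroid_hormone", "drug-brand"),
    # uric acid inhibitors
    ("allopurinol", "uric_acid_inhibitor", "drug-generic"),
    ("febuxostat", "uric_acid_inhibitor", "drug-generic"),
    ("zyloric", "uric_acid_inhibitor", "drug-brand"),
    ("adenuric", "uric_acid_inhibitor", "drug-brand"),
]

# (term, code, language)
CONDITION_ENTRIES = [
    ("hyperlipidemia", "hyperlipidemia", "en"),
    ("hypercholesterolemia", "hyperlipidemia", "en"),
    ("hyperlipidaemie", "hyperlipidemia", "de"),
    ("hypercholesterinaemie", "hyperlipidemia", "de"),
    ("hypertension", "hypertension", "en"),
    ("arterial hypertension", "hypertension", "en"),
    ("arterielle hypertonie", "hypertension", "de"),
    ("bluthochdruck", "hypertension", "de"),
    ("diabetes mellitus", "diabetes", "en"),
    ("diabetes", "diabetes", "en"),
    ("zuckerkrankheit", "diabetes", "de"),
    ("coronary heart disease", "coronary_heart_disease", "en"),
    ("coronary artery disease", "coronary_heart_disease", "en"),
    ("koronare herzkrankheit", "coronary_heart_disease", "de"),
    ("congestive heart failure", "congestive_heart_failure", "en"),
    ("heart failure", "congestive_heart_failure", "en"),
    ("herzinsuffizienz", "congestive_heart_failure", "de"),
    ("vascular disease", "vascular_disease", "en"),
    ("stroke", "vascular_disease", "en"),
    ("carotid stenosis", "vascular_disease", "en"),
    ("peripheral artery disease", "vascular_disease", "en"),
    ("schlaganfall", "vascular_disease", "de"),
    ("karotisstenose", "vascular_disease", "de"),
    ("chronic kidney disease", "chronic_kidney_disease", "en"),
    ("renal insufficiency", "chronic_kidney_disease", "en"),
    ("niereninsuffizienz", "chronic_kidney_disease", "de"),
    ("pulmonary disease", "pulmonary_disease", "en"),
    ("chronic obstructive pulmonary disease", "pulmonary_disease", "en"),
    ("lungenerkrankung", "pulmonary_disease", "de"),
    ("hip osteoarthritis", "osteoarthritis", "en"),
    ("knee osteoarthritis", "osteoarthritis", "en"),
    ("gonarthrose", "osteoarthritis", "de"),
    ("coxarthrose", "osteoarthritis", "de"),
    ("parkinson disease", "parkinson", "en"),
    ("morbus parkinson", "parkinson", "de"),
    ("low back pain", "low_back_pain", "en"),
    ("lumbago", "low_back_pain", "en"),
    ("rueckenschmerzen", "low_back_pain", "de"),
    ("depression", "depression", "en"),
    ("depressive episode", "depression", "en"),
    ("depressive stoerung", "depression", "de"),
]

DRUG_CLASSES = sorted({code for _, code, _ in DRUG_ENTRIES})
CONDITIONS = sorted({code for _, code, _ in CONDITION_ENTRIES})

assert len(DRUG_CLASSES) == 22
assert len(CONDITIONS) == 12
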