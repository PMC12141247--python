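# CPIC-style statin recommendations keyed on the SLCO1B1 phenotype.
# Rosuvastatin rows additionally key on ABCG2 and fluvastatin rows on
# CYP2C9; those genes default to a Normal Metabolizer profile when absent
# from the query (see default_profiles.tsv).
# "Poor function" rows are synthetic placeholder entries that keep lookup
# total over the Normal/Decreased/Poor phenotype range; consult the current
# guideline for clinical use.
drug	profile	recommendation
simvastatin	SLCO1B1:Normal function	Prescribe desired starting dose and adjust doses based on disease-specific guidelines
simvastatin	SLCO1B1:Decreased function	Prescribe an alternative statin depending on the desired potency. If simvastatin therapy is warranted, limit dose to < 20 mg/day
simvastatin	SLCO1B1:Poor function	Prescribe an alternative statin depending on the desired potency (synthetic placeholder entry)
rosuvastatin	SLCO1B1:Normal function;ABCG2:Normal Metabolizer	Prescribe desired starting dose and adjust doses of rosuvastatin based on disease-specific and specific population guidelines
rosuvastatin	SLCO1B1:Decreased function;ABCG2:Normal Metabolizer	Prescribe desired starting dose and adjust doses of rosuvastatin based on disease-specific and specific population guidelines. Prescriber should be aware of possible increased risk for myopathy especially for doses > 20 mg
rosuvastatin	SLCO1B1:Poor function;ABCG2:Normal Metabolizer	Prescribe a reduced starting dose of rosuvastatin and adjust doses based on disease-specific guidelines (synthetic placeholder entry)
lovastatin	SLCO1B1:Normal function	Prescribe desired starting dose and adjust doses based on disease-specific guidelines
lovastatin	SLCO1B1:Decreased function	Prescribe an alternative statin depending on the desired potency. If lovastatin therapy is warranted, limit dose to ≤ 20 mg/day
lovastatin	SLCO1B1:Poor function	Prescribe an alternative statin depending on the desired potency (synthetic placeholder entry)
pravastatin	SLCO1B1:Normal function	Prescribe desired starting dose and adjust doses based on disease-specific guidelines
pravastatin	SLCO1B1:Decreased function	Prescribe desired starting dose and adjust doses of pravastatin based on disease-specific guidelines. Prescriber should be aware of possible increased risk for myopathy with pravastatin especially with doses > 40 mg per day
pravastatin	SLCO1B1:Poor function	Prescribe a reduced starting dose of pravastatin and adjust doses based on disease-specific guidelines (synthetic placeholder entry)
atorvastatin	SLCO1B1:Normal function	Prescribe desired starting dose and adjust doses based on disease-specific guidelines
atorvastatin	SLCO1B1:Decreased function	Prescribe ≤ 40 mg as a starting dose and adjust doses of atorvastatin based on disease-specific guidelines. Prescriber should be aware of possible increased risk for myopathy especially for 40 mg dose. If dose > 40 mg needed for desired efficacy, consider combination therapy (i.e., atorvastatin plus non-statin guideline directed medical therapy)
atorvastatin	SLCO1B1:Poor function	Prescribe ≤ 20 mg as a starting dose and adjust doses of atorvastatin based on disease-specific guidelines (synthetic placeholder entry)
fluvastatin	SLCO1B1:Normal function;CYP2C9:Normal Metabolizer	Prescribe desired starting dose and adjust doses of fluvastatin based on disease-specific guidelines
fluvastatin	SLCO1B1:Decreased function;CYP2C9:Normal Metabolizer	Prescribe desired starting dose and adjust doses of fluvastatin based on disease-specific guidelines. Prescriber should be aware of possible increased risk for myopathy especially for doses > 40 mg per day
fluvastatin	SLCO1B1:Poor function;CYP2C9:Normal Metabolizer	Prescribe an alternative statin or limit fluvastatin dose (synthetic placeholder entry)
pitavastatin	SLCO1B1:Normal function	Prescribe desired starting dose and adjust doses based on disease-specific guidelines
pitavastatin	SLCO1B1:Decreased function	Prescribe ≤ 2 mg as a starting dose and adjust doses of pitavastatin based on disease-specific guidelines. Prescriber should be aware of possible increased risk for myopathy especially for doses > 1 mg. If dose > 2 mg needed for desired efficacy, consider an alternative statin or combination therapy (i.e., pitavastatin plus non-statin guideline directed medical therapy)
pitavastatin	SLCO1B1:Poor function	Prescribe ≤ 1 mg as a starting dose and adjust doses of pitavastatin based on disease-specific guidelines (synthetic placeholder entry)
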