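code,label,parent
drug,Drug,
small_molecule,Small Molecule,drug
monoclonal_antibody,Monoclonal Antibody,drug
other_pharma,Other Pharmacologic,drug
conventional,Conventional,
pdac_combination_or_delivery,PDAC Combination/Delivery,conventional
fda_approved_other_cancer,FDA-Approved (Other Cancer),conventional
radiation,Radiation,conventional
gene_therapy,Gene Therapy,
cellular_therapy,Cellular Therapy,
nutraceutical,Nutraceutical,
procedure,Technique/Procedure,
pain_qol,Pain/Quality of Life,
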