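code,label,parent
immune,Immune System,
checkpoint,Checkpoint Inhibitor,immune
adoptive_cell,Adoptive Cell,immune
t_cell,T-Cell,adoptive_cell
adoptive_other,Other Adoptive Cell,adoptive_cell
oncolytic_virus,Oncolytic Virus,immune
vaccine,Cancer Vaccine,immune
other_immune,Other Immune,immune
dna_cell_cycle,DNA and Cell Cycle,
cell_signaling,Cell Signaling,
rtk,RTKs,cell_signaling
ras_raf_mek_erk,KRAS/RAF/ERK/MEK,cell_signaling
pi3k_akt_mtor,PI3K/AKT/mTOR,cell_signaling
jak_stat,JAK-STAT,cell_signaling
fak_src,FAK/SRC,cell_signaling
misc_signaling,Misc. Signaling,cell_signaling
metabolism,Metabolism,
angiogenesis,Angiogenesis,
hormone_receptor,Hormone Receptors,
apoptosis,Apoptosis Specific,
symptom,Target Symptoms,
thrombosis,Thrombosis,symptom
infection,Infection,symptom
enzyme_supplementation,Enzyme Supplementation,symptom
metastasis_invasion,Metastasis/Invasion,
unknown,Unknown Mechanism,
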