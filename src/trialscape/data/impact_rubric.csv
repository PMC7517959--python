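criterion,level,points
novelty,novel_mechanism_pdac,5
novelty,novel_drug_or_indication_pdac,2
novelty,beyond_standard_of_care,1
novelty,established,0
promise,phase3_success_other,2
promise,untested_or_under_investigation,0
promise,any_phase_failure_other,-2
allocation,randomized,1
allocation,not_applicable,0
allocation,non_randomized,-1
pfs_improvement,gt6mo,2
pfs_improvement,one_to_6mo,1
pfs_improvement,lt1mo,0
os_improvement,gt6mo,2
os_improvement,one_to_6mo,1
os_improvement,lt1mo,0
susceptibility,gt30pct,3
susceptibility,pct5_to_30,2
susceptibility,lt5pct,1
desired_impact,direct_treat,3
desired_impact,procedural_or_sequencing,1
desired_impact,symptoms_or_sequelae,0
trial_status,active,0
trial_status,terminated_and_published,-5
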