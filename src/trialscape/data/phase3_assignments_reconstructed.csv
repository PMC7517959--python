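registry_id,novelty,promise,allocation,pfs_improvement,os_improvement,susceptibility,desired_impact,trial_status,pfs_delta_months,os_delta_months,susceptible_fraction
NCT03377491,novel_mechanism_pdac,phase3_success_other,non_randomized,one_to_6mo,gt6mo,gt30pct,direct_treat,active,4.6,8.2,0.9
NCT03504423,novel_mechanism_pdac,untested_or_under_investigation,non_randomized,one_to_6mo,gt6mo,gt30pct,direct_treat,active,,7.9,0.9
NCT03126435,novel_drug_or_indication_pdac,phase3_success_other,non_randomized,one_to_6mo,one_to_6mo,gt30pct,direct_treat,active,1.9,1.9,0.9
NCT03766295,novel_mechanism_pdac,untested_or_under_investigation,non_randomized,lt1mo,lt1mo,gt30pct,direct_treat,active,,,0.9
NCT02184195,novel_drug_or_indication_pdac,untested_or_under_investigation,randomized,one_to_6mo,lt1mo,pct5_to_30,direct_treat,active,3.6,0.8,0.07
NCT02948309,novel_drug_or_indication_pdac,untested_or_under_investigation,randomized,lt1mo,lt1mo,gt30pct,direct_treat,active,,,0.9
NCT01926197,beyond_standard_of_care,untested_or_under_investigation,randomized,one_to_6mo,lt1mo,gt30pct,direct_treat,active,,,0.9
NCT01077427,beyond_standard_of_care,untested_or_under_investigation,randomized,lt1mo,lt1mo,gt30pct,direct_treat,active,,,0.9
NCT03251365,beyond_standard_of_care,untested_or_under_investigation,randomized,lt1mo,lt1mo,gt30pct,direct_treat,active,,,0.9
NCT03649035,beyond_standard_of_care,untested_or_under_investigation,randomized,lt1mo,lt1mo,gt30pct,direct_treat,active,,,0.9
NCT03398291,beyond_standard_of_care,untested_or_under_investigation,randomized,one_to_6mo,one_to_6mo,gt30pct,procedural_or_sequencing,active,,,0.9
NCT03721744,novel_drug_or_indication_pdac,any_phase_failure_other,randomized,lt1mo,lt1mo,gt30pct,direct_treat,active,,,0.9
NCT02923921,novel_drug_or_indication_pdac,untested_or_under_investigation,non_randomized,lt1mo,lt1mo,gt30pct,direct_treat,active,,,0.9
NCT03468335,beyond_standard_of_care,untested_or_under_investigation,not_applicable,lt1mo,lt1mo,gt30pct,direct_treat,active,,,0.9
NCT01964430,beyond_standard_of_care,untested_or_under_investigation,not_applicable,lt1mo,lt1mo,gt30pct,direct_treat,active,,,0.9
NCT02993731,novel_drug_or_indication_pdac,any_phase_failure_other,not_applicable,lt1mo,lt1mo,gt30pct,direct_treat,active,,,0.9
NCT03610100,beyond_standard_of_care,untested_or_under_investigation,non_randomized,lt1mo,lt1mo,gt30pct,direct_treat,active,,,0.9
NCT03257033,beyond_standard_of_care,untested_or_under_investigation,non_randomized,lt1mo,lt1mo,gt30pct,direct_treat,active,,,0.9
NCT02201381,novel_drug_or_indication_pdac,any_phase_failure_other,randomized,lt1mo,lt1mo,pct5_to_30,direct_treat,active,,,0.2
NCT01954992,beyond_standard_of_care,untested_or_under_investigation,non_randomized,lt1mo,lt1mo,gt30pct,direct_treat,active,,,0.9
NCT01013649,beyond_standard_of_care,untested_or_under_investigation,randomized,lt1mo,lt1mo,gt30pct,procedural_or_sequencing,active,,,0.9
NCT02539537,established,untested_or_under_investigation,randomized,lt1mo,lt1mo,gt30pct,procedural_or_sequencing,active,,,0.9
NCT02853474,beyond_standard_of_care,untested_or_under_investigation,randomized,lt1mo,lt1mo,gt30pct,symptoms_or_sequelae,active,,,0.9
NCT03472833,novel_drug_or_indication_pdac,untested_or_under_investigation,non_randomized,lt1mo,lt1mo,gt30pct,symptoms_or_sequelae,active,,,0.9
NCT01827553,established,untested_or_under_investigation,not_applicable,lt1mo,lt1mo,gt30pct,procedural_or_sequencing,active,,,0.9
NCT02195232,novel_drug_or_indication_pdac,untested_or_under_investigation,non_randomized,lt1mo,lt1mo,gt30pct,symptoms_or_sequelae,active,,,0.9
NCT02404363,novel_drug_or_indication_pdac,untested_or_under_investigation,non_randomized,lt1mo,lt1mo,pct5_to_30,symptoms_or_sequelae,active,,,0.2
NCT02919787,established,untested_or_under_investigation,not_applicable,lt1mo,lt1mo,pct5_to_30,procedural_or_sequencing,active,,,0.15
NCT02172976,established,untested_or_under_investigation,not_applicable,lt1mo,lt1mo,pct5_to_30,procedural_or_sequencing,active,,,0.15
NCT02506842,established,untested_or_under_investigation,not_applicable,lt1mo,lt1mo,pct5_to_30,procedural_or_sequencing,active,,,0.15
NCT02457156,established,untested_or_under_investigation,randomized,lt1mo,lt1mo,lt5pct,procedural_or_sequencing,active,,,0.04
NCT02514928,established,untested_or_under_investigation,randomized,lt1mo,lt1mo,lt5pct,procedural_or_sequencing,active,,,0.04
NCT02871804,established,untested_or_under_investigation,randomized,lt1mo,lt1mo,lt5pct,procedural_or_sequencing,active,,,0.04
NCT03269994,established,untested_or_under_investigation,randomized,lt1mo,lt1mo,lt5pct,symptoms_or_sequelae,active,,,0.04
NCT03434678,established,untested_or_under_investigation,randomized,lt1mo,lt1mo,lt5pct,symptoms_or_sequelae,active,,,0.04
NCT02340728,established,untested_or_under_investigation,non_randomized,lt1mo,lt1mo,lt5pct,symptoms_or_sequelae,active,,,0.04
NCT02349412,established,untested_or_under_investigation,non_randomized,lt1mo,lt1mo,lt5pct,symptoms_or_sequelae,active,,,0.04
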