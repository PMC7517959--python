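year,intervention,palliative_survival_months,adjuvant_survival_benefit_months
1962,Fluorouracil,4.41,11 vs. 20
1997,Gemcitabine,4.41 vs. 5.65,20.2 vs. 22.8
2005,Erlotinib + Gemcitabine,5.91 vs. 6.24,No benefit
2011,FOLFIRINOX,6.8 vs. 11.1,35.0 vs 54.4
2013,Nab-paclitaxel + Gemcitabine,6.7 vs. 8.5,36.2 vs. 40.5
2015,Liposomal Irinotecan,4.2 vs. 6.1,
2019,Olaparib,18.1 vs. 18.9,
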