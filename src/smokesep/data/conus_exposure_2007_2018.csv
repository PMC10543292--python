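year,total_pop,pop_no_aqs,smoke_impacted_pop,smoke_impacted_pop_no_aqs,impact_days_aqs,impact_days_no_aqs,mean_total_pm_aqs,mean_smoke_pm_aqs,mean_total_pm_no_aqs,mean_smoke_pm_no_aqs
2007,300.1,73.6,299.7,73.6,38.2,54.6,11.90,0.96,9.87,1.11
2008,302.6,74.1,298.3,72.6,21.2,22.4,10.42,0.32,8.26,0.38
2009,305.5,70.9,300.3,69.9,13.5,19.4,11.20,0.25,8.45,0.22
2010,307.0,72.0,285.7,71.6,12.8,22.6,10.83,0.57,9.73,0.77
2011,310.0,72.9,307.9,72.7,16.4,25.7,11.43,0.51,9.14,0.73
2012,299.9,72.0,289.0,71.6,11.9,20.3,10.35,0.53,9.28,0.83
2013,313.1,74.0,308.0,72.9,16.7,19.1,11.57,0.61,9.34,0.66
2014,317.3,74.6,310.8,74.3,16.9,22.5,9.40,0.31,8.74,0.40
2015,319.8,74.9,313.2,74.6,14.4,19.2,9.37,0.48,7.91,0.64
2016,321.5,74.9,319.7,74.9,17.6,25.0,9.30,0.31,7.98,0.48
2017,324.1,74.6,321.6,74.5,26.2,33.8,11.22,0.97,8.78,0.92
2018,325.6,74.8,308.9,73.1,20.2,18.5,10.51,0.61,8.95,0.65
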