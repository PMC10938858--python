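county,state,group,Population,MedianAge,%White,%AfricanAmerican,%Female,svi
Orange County,CA,high,1.00,0.22,0.08,0.54,0.49,0.90
Salt Lake County,UT,high,0.99,0.05,0.32,0.54,0.74,0.90
Pinellas County,FL,high,0.98,0.90,0.36,0.25,0.07,0.90
Suffolk County,NY,high,1.00,0.19,0.04,0.48,0.76,0.90
Santa Clara County,CA,high,0.99,0.50,0.29,0.30,0.37,0.90
Beckham County,OK,low,0.02,0.16,0.43,0.49,0.97,0.08
Conway County,AR,low,0.02,0.69,0.51,0.26,0.38,0.08
New Madrid County,MO,low,0.01,0.67,0.48,0.19,0.05,0.06
Jones County,TX,low,0.01,0.42,0.17,0.24,0.99,0.06
Todd County,SD,low,0.01,0.01,0.01,0.94,0.25,0.05
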