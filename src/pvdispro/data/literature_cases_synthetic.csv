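drug,age_years,sex,latency_days,hospitalized,outcome
CIPROFLOXACIN,72,F,4,true,Recovered after drug withdrawal
CIPROFLOXACIN,81,M,14,true,Recovered after drug withdrawal
CIPROFLOXACIN,68,F,21,false,Improved with topical corticosteroids
LEVOFLOXACIN,38,F,10,true,Recovered after drug withdrawal
LEVOFLOXACIN,77,M,18,false,Improved with topical corticosteroids
OFLOXACIN,70,F,25,true,Recovered after drug withdrawal
OFLOXACIN,84,M,30,false,Recovered after drug withdrawal
MOXIFLOXACIN,58,F,18,true,Recovered after drug withdrawal
NORFLOXACIN,79,M,28,false,Improved with topical corticosteroids
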