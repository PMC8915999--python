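person_id,sex,birth_date,death_date,birth_place,death_place
r01,male,1700-03-10,1765-05-20,Berlin,Berlin
r02,male,1700-03-10,1765-05-20,BERLIN.,Berlin
r03,male,1710-01-01,1770-01-01,Potsdam,Berlin
r04,male,1710-01-01,1770-01-01, potsdam,Spandau
r05,male,1711-02-02,1814-03-03,Berlin,Berlin
r06,male,1850-01-01,1920-06-01,Berlin,Berlin
r07,male,1720-07-07,1780-08-08,Spandau,Berlin
r08,male,1730-04-04,1795-09-09,Berlin,Potsdam
r09,male,1740-05-05,1805-10-10,Potsdam,Potsdam
r10,male,1750-06-06,1840-11-11,Berlin,Spandau
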