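district_code,county,census_population_15plus,qof_sm07_population,n_practices,ihs_sample_size
Blaby,Leicestershire,77600,67895,9,301
Charnwood,Leicestershire,139800,152533,24,396
Harborough,Leicestershire,70200,69168,8,234
Hinckley and Bosworth,Leicestershire,87800,84159,12,305
Melton,Leicestershire,41900,34912,2,130
North West Leicestershire,Leicestershire,77000,78331,14,242
Oadby and Wigston,Leicestershire,47100,48054,9,167
Corby,Northamptonshire,49400,57112,5,131
Daventry,Northamptonshire,64100,71902,8,223
East Northamptonshire,Northamptonshire,70900,55279,8,217
Kettering,Northamptonshire,75900,87059,9,180
Northampton,Northamptonshire,171600,184370,27,446
South Northamptonshire,Northamptonshire,69700,60391,8,205
Wellingborough,Northamptonshire,61300,61013,9,172
Leicester,Unitary Authority,264600,293156,59,1475
Rutland,Unitary Authority,31300,29628,4,416
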