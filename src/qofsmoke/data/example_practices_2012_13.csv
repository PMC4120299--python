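practice_id,year,postcode,indicator,numerator,denominator
A,2012/13,,SM07,3450,3721
A,2012/13,,SM08,1024,1129
B,2012/13,,SM07,1319,1497
B,2012/13,,SM08,325,401
C,2012/13,,SM07,6276,7033
C,2012/13,,SM08,1578,1586
D,2012/13,,SM07,31948,37654
D,2012/13,,SM08,8439,10931
E,2012/13,,SM07,6504,7212
E,2012/13,,SM08,2165,2373
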