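age_min_days,age_max_days,sex,upper_limit_umol_l
29,365,any,36
365,1095,any,36
1095,1825,any,44
1825,2555,any,47
2555,3285,any,53
3285,4015,any,58
4015,4745,any,65
4745,5475,any,73
5475,6570,any,84
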