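compound_id,role,pki_observed,pki_predicted,apd_distance
AM-694,train,6.553,6.474,
CRA-13,train,6.319,6.816,
"CP47,497-C6",train,4.921,5.174,
"CP47,497",train,6.066,6.075,
"CP47,497-C8",train,6.921,6.308,
CRA13-F,train,7.097,6.687,
CRA13-OH,train,5.268,5.160,
RCS-4,train,4.921,5.26,
JWH-073,train,6.638,6.688,
JWH-081,train,7.208,6.92,
JWH-210,train,7.658,8.007,
"CP47,497-C9",test,6.319,6.773,1.903
JWH-018,test,7.638,7.253,2.887
THC,test,6.678,6.917,3.917
JWH-015,excluded_outlier,2.252,,
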