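# Published benchmark: isocenter chamber-dose ratios for ten induced MLC error
# classes on a five-beam sliding-window prostate plan.  dcalc_ratio is the
# log-reconstructed-plan dose over the reference-plan dose (both TPS-computed);
# dmeas_ratio is the measured erroneous-delivery dose over the measured
# reference-delivery dose.
error,label,dcalc_ratio,dmeas_ratio
1,1 mm MLC opening,1.038,1.039
2,2 mm MLC opening,1.077,1.077
3,4 mm MLC opening,1.154,1.153
4,0.5 mm shift bank A,1.019,1.019
5,1 mm shift bank A,1.037,1.036
6,2 mm shift bank A,1.074,1.071
7,0.5 mm shift bank B,1.019,1.020
8,1 mm shift bank B,1.039,1.040
9,2 mm shift bank B,1.079,1.077
10,Segments missing,0.997,0.993
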