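# Published benchmark: target DVH metrics (percent of prescription dose) for 20
# clinical sliding-window plans at four sites, comparing each original plan with
# its log-reconstructed counterpart, plus the maximum per-leaf RMS positional
# error (cm) of the delivery reported by the vendor log-viewer analysis.
case,max_rms_cm,d98_orig,d98_recon,d2_orig,d2_recon,dmean_orig,dmean_recon
HN1,0.035,92.4,92.3,105.6,105.5,100.0,100.0
HN2,0.059,92.6,92.6,103.0,102.9,100.3,100.2
HN3,0.056,94.7,94.6,103.7,103.7,100.0,100.1
HN4,0.056,90.5,90.5,105.1,105.1,100.0,100.0
HN5,0.032,93.7,93.4,105.3,105.0,100.0,99.8
Prost1,0.033,96.5,96.5,102.0,102.1,100.0,100.1
Prost2,0.053,94.9,95.0,101.9,102.0,100.0,100.1
Prost3,0.028,96.0,95.9,102.3,102.3,100.0,99.9
Prost4,0.049,95.3,95.4,102.6,102.6,100.0,100.0
Prost5,0.044,95.3,95.3,102.8,102.8,100.0,100.0
Breast1,0.024,91.8,91.6,104.7,104.6,100.0,99.9
Breast2,0.022,92.5,92.7,105.8,106.0,100.0,100.2
Breast3,0.030,94.0,93.8,104.6,104.4,100.0,99.8
Breast4,0.017,90.6,90.8,105.9,106.3,100.0,100.5
Breast5,0.030,92.5,92.4,103.2,103.1,100.0,100.0
Lung1,0.037,90.4,90.3,106.0,105.9,100.0,99.9
Lung2,0.007,102.4,102.4,126.0,126.0,117.0,117.1
Lung3,0.020,95.1,96.1,103.5,103.4,100.0,100.0
Lung4,0.015,101.6,101.7,123.4,123.5,113.7,113.8
Lung5,0.021,97.5,97.3,120.8,120.8,109.3,109.2
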