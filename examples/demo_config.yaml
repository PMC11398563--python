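# Shipped demo configuration: study-default thresholds, desk-scale sizes.
n_peaks: 2000
pi1: 0.1
spike_log2fc: 2.0
q: 0.30
fc_threshold: 2.0
lfdr_threshold: 0.3
span: 0.5
null_mode: empirical
bin_size: 1000
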