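Experiment 1 (spacing)  n = 2
Context       Climbing rate (uV/s)     Peak latency (ms)   Peak amplitude (uV)   Mean amplitude (uV)              PSE (ms)              JND (ms)
Short (PS)           -23.0 +/- 0.0         567.1 +/- 0.0          -8.3 +/- 0.0        -4.93 +/- 0.00         854.0 +/- 3.2         125.9 +/- 3.8
Long (NS)            -20.0 +/- 0.0         652.9 +/- 0.0          -9.0 +/- 0.0        -5.63 +/- 0.00        954.2 +/- 32.1         135.9 +/- 1.9
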