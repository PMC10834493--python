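# Compendial paddle-method parameters for the bundled vildagliptin study.
# Metadata only: no computation depends on these values.
medium: 0.01 N HCl
volume_ml: 1000
apparatus: USP 2 (paddle)
speed_rpm: 50
temp_c: 37
detection: HPLC (210 nm)
time_interval_min: [10, 15, 20, 30, 45]
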