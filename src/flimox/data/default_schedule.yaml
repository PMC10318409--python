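# Default oxygen step-test programme: setpoints in % O2, 4 h initial hold,
# 3 h per subsequent step, one FLIM frame every 5 min.
levels_percent: [0, 2, 4, 6, 8, 10, 15, 21, 100]
initial_hold_h: 4.0
step_duration_h: 3.0
sample_interval_min: 5.0
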