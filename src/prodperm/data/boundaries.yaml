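# Default LBCS bin boundaries (log10 units).  These are calibration
# values chosen so that the study's qualitative bin placements hold
# (cytarabine red, CytO4 green, CytO12-16 and abiraterone yellow,
# paliperidone too permeable); the published diagram draws the regions
# graphically without printing numbers.
logPerm_too_fast: -7.5
logPerm_too_slow: -10.5
logK_membrane_trapped: 3.5
logK_green_min: -2.0
logK_green_max: 3.5
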