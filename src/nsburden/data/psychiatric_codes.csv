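condition,icd_version,code_prefix
anxiety,10,F411
anxiety,10,F418
anxiety,10,F419
anxiety,10,F064
anxiety,9,30000
anxiety,9,30002
anxiety,9,30009
panic,10,F410
panic,9,30001
depression,10,F32
depression,10,F33
depression,9,2962
depression,9,2963
depression,9,311
bipolar,10,F31
bipolar,9,2964
bipolar,9,2965
bipolar,9,2966
bipolar,9,2967
ptsd,10,F431
ptsd,9,30981
substance_use,10,F10
substance_use,10,F11
substance_use,10,F12
substance_use,10,F13
substance_use,10,F14
substance_use,10,F15
substance_use,10,F16
substance_use,10,F18
substance_use,10,F19
substance_use,9,303
substance_use,9,304
substance_use,9,3050
substance_use,9,3052
substance_use,9,3053
substance_use,9,3054
substance_use,9,3055
substance_use,9,3056
substance_use,9,3057
substance_use,9,3058
substance_use,9,3059
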