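video_id,surgeon_id,true_group,cholecystic_vascular_injury
V001,A,competent,0
V002,A,competent,0
V003,B,competent,1
V004,B,competent,0
V005,C,incompetent,0
V006,C,incompetent,1
V007,D,competent,0
V008,D,competent,0
V009,E,competent,0
V010,E,competent,0
V011,F,competent,0
V012,F,competent,0
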