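video_id,rater_id,dp,bd,eff,th
V001,R1,4,4,4,4
V001,R2,4,5,4,4
V002,R1,4,4,5,4
V002,R2,4,4,4,4
V003,R1,3,3,3,3
V003,R2,3,3,2,3
V004,R1,3,3,3,4
V004,R2,3,4,3,3
V005,R1,2,2,2,2
V005,R2,2,2,3,2
V006,R1,1,2,1,2
V006,R2,2,2,1,2
V007,R1,4,4,4,3
V007,R2,4,3,4,4
V008,R1,4,4,3,4
V008,R2,3,4,4,4
V009,R1,4,4,4,4
V009,R2,4,4,5,4
V010,R1,3,4,3,3
V010,R2,4,3,3,3
V011,R1,5,5,5,5
V011,R2,5,5,4,5
V012,R1,4,5,4,5
V012,R2,5,4,5,4
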