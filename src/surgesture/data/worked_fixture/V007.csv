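#meta {"metadata": {"cvs_score": 3, "intraop_events": [], "parkland_grade": 1}, "phase_durations": {"DGB": 60.0, "MHT": 60.0}, "surgeon_id": "D", "video_id": "V007"}
video_id,surgeon_id,phase,label,hand,start_s,end_s
V007,D,MHT,hook,unattributed,0.0,10.0
V007,D,MHT,hook,unattributed,20.0,30.0
V007,D,MHT,hook,unattributed,50.0,60.0
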