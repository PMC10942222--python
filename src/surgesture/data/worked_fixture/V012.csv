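#meta {"metadata": {"cvs_score": 1, "intraop_events": [], "parkland_grade": 1}, "phase_durations": {"DGB": 50.0, "MHT": 20.0}, "surgeon_id": "F", "video_id": "V012"}
video_id,surgeon_id,phase,label,hand,start_s,end_s
V012,F,DGB,hook,unattributed,0.0,15.0
V012,F,DGB,grasp,right,16.0,30.0
V012,F,DGB,hook,unattributed,31.0,45.0
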