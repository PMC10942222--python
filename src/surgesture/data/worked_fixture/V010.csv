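#meta {"metadata": {"cvs_score": 6, "intraop_events": [], "parkland_grade": 1}, "phase_durations": {"DGB": 20.0, "MHT": 30.0}, "surgeon_id": "E", "video_id": "V010"}
video_id,surgeon_id,phase,label,hand,start_s,end_s
V010,E,MHT,grasp,right,0.0,30.0
V010,E,MHT,hook,unattributed,0.0,30.0
V010,E,DGB,grasp,right,0.0,20.0
V010,E,DGB,hook,unattributed,5.0,20.0
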