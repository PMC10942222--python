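#meta {"metadata": {"cvs_score": 2, "intraop_events": [], "parkland_grade": 1}, "phase_durations": {"DGB": 30.0, "MHT": 30.0}, "surgeon_id": "A", "video_id": "V002"}
video_id,surgeon_id,phase,label,hand,start_s,end_s
V002,A,MHT,hook,unattributed,0.0,10.0
V002,A,MHT,hook,unattributed,10.0,20.0
V002,A,MHT,blunt_dissection,unattributed,20.0,30.0
V002,A,DGB,grasp,left,0.0,15.0
V002,A,DGB,inefficient_grasp,left,15.0,30.0
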