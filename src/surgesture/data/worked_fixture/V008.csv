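#meta {"metadata": {"cvs_score": 5, "intraop_events": [], "parkland_grade": 1}, "phase_durations": {"DGB": 60.0, "MHT": 60.0}, "surgeon_id": "D", "video_id": "V008"}
video_id,surgeon_id,phase,label,hand,start_s,end_s
V008,D,MHT,hook,unattributed,0.0,10.0
V008,D,MHT,grasp,left,12.0,20.0
V008,D,MHT,hook,unattributed,22.0,30.0
V008,D,MHT,grasp,left,32.0,40.0
V008,D,MHT,hook,unattributed,42.0,50.0
V008,D,MHT,grasp,left,52.0,60.0
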