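#meta {"metadata": {"cvs_score": 1, "intraop_events": [], "parkland_grade": 1}, "phase_durations": {"DGB": 20.0, "MHT": 60.0}, "surgeon_id": "B", "video_id": "V004"}
video_id,surgeon_id,phase,label,hand,start_s,end_s
V004,B,MHT,grasp,left,5.0,25.0
V004,B,MHT,push,right,10.0,30.0
V004,B,MHT,hook,unattributed,40.0,55.0
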