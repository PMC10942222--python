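#meta {"metadata": {"cvs_score": 0, "intraop_events": ["cholecystic_vascular_injury"], "parkland_grade": 2}, "phase_durations": {"DGB": 55.0, "MHT": 45.0}, "surgeon_id": "B", "video_id": "V003"}
video_id,surgeon_id,phase,label,hand,start_s,end_s
V003,B,MHT,hook,unattributed,0.0,20.0
V003,B,MHT,coagulate,unattributed,25.0,40.0
V003,B,DGB,blunt_dissection,unattributed,0.0,30.0
V003,B,DGB,spread,right,35.0,50.0
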