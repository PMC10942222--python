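#meta {"metadata": {"cvs_score": 0, "intraop_events": ["cholecystic_vascular_injury", "gallbladder_broken"], "parkland_grade": 2}, "phase_durations": {"DGB": 40.0, "MHT": 50.0}, "surgeon_id": "C", "video_id": "V006"}
video_id,surgeon_id,phase,label,hand,start_s,end_s
V006,C,MHT,inefficient_grasp,right,0.0,8.0
V006,C,MHT,inefficient_grasp,right,12.0,20.0
V006,C,MHT,inefficient_hook,unattributed,22.0,30.0
V006,C,MHT,push,right,32.0,45.0
V006,C,DGB,inefficient_hook,unattributed,0.0,18.0
V006,C,DGB,pull,right,20.0,33.0
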