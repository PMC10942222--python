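#meta {"metadata": {"cvs_score": 5, "intraop_events": [], "parkland_grade": 1}, "phase_durations": {"DGB": 22.0, "MHT": 40.0}, "surgeon_id": "F", "video_id": "V011"}
video_id,surgeon_id,phase,label,hand,start_s,end_s
V011,F,MHT,grasp,left,0.0,28.0
V011,F,MHT,hook,unattributed,1.0,10.0
V011,F,MHT,hook,unattributed,11.0,20.0
V011,F,MHT,hook,unattributed,21.0,27.0
V011,F,MHT,clip,unattributed,29.0,33.0
V011,F,MHT,cut,unattributed,34.0,36.0
V011,F,DGB,grasp,left,0.0,20.0
V011,F,DGB,blunt_dissection,unattributed,1.0,19.0
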