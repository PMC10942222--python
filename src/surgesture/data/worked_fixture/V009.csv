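#meta {"metadata": {"cvs_score": 2, "intraop_events": [], "parkland_grade": 1}, "phase_durations": {"DGB": 25.0, "MHT": 55.0}, "surgeon_id": "E", "video_id": "V009"}
video_id,surgeon_id,phase,label,hand,start_s,end_s
V009,E,MHT,retract,left,0.0,10.0
V009,E,MHT,spread,right,2.0,7.0
V009,E,MHT,irrigate,unattributed,12.0,18.0
V009,E,MHT,suction,unattributed,19.0,24.0
V009,E,MHT,pull,left,26.0,33.0
V009,E,MHT,clip,unattributed,34.0,38.0
V009,E,MHT,cut,unattributed,39.0,41.0
V009,E,MHT,coagulate,unattributed,42.0,50.0
V009,E,DGB,blunt_dissection,unattributed,0.0,12.0
V009,E,DGB,push,left,13.0,20.0
V009,E,DGB,push,right,14.0,22.0
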