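#meta {"metadata": {"cvs_score": 4, "intraop_events": ["liver_thermal_injury"], "parkland_grade": 1}, "phase_durations": {"DGB": 32.0, "MHT": 60.0}, "surgeon_id": "A", "video_id": "V001"}
video_id,surgeon_id,phase,label,hand,start_s,end_s
V001,A,MHT,grasp,left,0.0,12.0
V001,A,MHT,hook,unattributed,2.0,8.0
V001,A,MHT,inefficient_hook,unattributed,9.0,14.0
V001,A,MHT,push,right,12.5,18.0
V001,A,MHT,coagulate,unattributed,20.0,26.0
V001,A,MHT,grasp,left,30.0,44.0
V001,A,MHT,hook,unattributed,31.0,40.0
V001,A,MHT,clip,unattributed,46.0,52.0
V001,A,MHT,cut,unattributed,53.0,56.0
V001,A,DGB,grasp,left,0.0,15.0
V001,A,DGB,blunt_dissection,unattributed,1.0,9.0
V001,A,DGB,hook,unattributed,10.0,22.0
V001,A,DGB,push,right,16.0,24.0
V001,A,DGB,suction,unattributed,25.0,30.0
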