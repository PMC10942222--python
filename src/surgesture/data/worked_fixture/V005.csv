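#meta {"metadata": {"cvs_score": 0, "intraop_events": [], "parkland_grade": 1}, "phase_durations": {"DGB": 30.0, "MHT": 90.0}, "surgeon_id": "C", "video_id": "V005"}
video_id,surgeon_id,phase,label,hand,start_s,end_s
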